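"""Model / Results interface tying the pipeline together.

:class:`DnaElasticNetwork` is constructed from a sequence (plus parameter
tables) and owns the basic structure, the spring network and its Hessian;
``fit()`` performs the normal-mode / covariance analysis and returns a
:class:`NormalModeResults` carrying every fluctuation profile, a summary
table, TSV export and plotting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import indices as idx_mod
from .helix import (
    BasicStructure,
    HelicalParameterSet,
    PlacementConfig,
    build_basic_structure,
)
from .indices import PairFrames, index_suite, pair_frames
from .network import (
    ConnectivityTable,
    ElasticNetworkModel,
    Hessian,
    build_hessian,
    build_model,
    default_connectivity,
)
from .nma import (
    DEFAULT_TEMPERATURE,
    CovarianceSource,
    NormalModes,
    PseudoinverseCovariance,
    normal_modes,
)
from .sequence import DnaSequence

#: pairs removed from each chain end before any profile is reported
END_TRIM_PAIRS = 2

#: above this dof count fit() switches from full diagonalization to the
#: sparse pseudoinverse solver (identical covariances, no mode spectrum)
AUTO_SOLVER_DOF = 1500


class DnaElasticNetwork:
    """A 1PkN elastic-network model of one DNA sequence.

    Parameters
    ----------
    sequence : DnaSequence or str
        Unambiguous A/C/G/T sequence (Watson strand).
    k : int
        Coarse-graining level: one particle per k nucleotides per strand.
    connectivity : ConnectivityTable, optional
        Spring classes and constant; defaults to the published table for k.
    helical_params, placement :
        Geometry of the basic structure; defaults are the packaged
        crystal-derived step parameters and canonical B-DNA atom placement.
    """

    def __init__(
        self,
        sequence,
        k: int = 3,
        connectivity: ConnectivityTable | None = None,
        helical_params: HelicalParameterSet | None = None,
        placement: PlacementConfig | None = None,
        temperature: float = DEFAULT_TEMPERATURE,
        mass: float = 1.0,
        structure: BasicStructure | None = None,
        bend_projection: str = "t",
    ):
        if isinstance(sequence, str):
            sequence = DnaSequence(sequence)
        self.sequence = sequence
        self.k = k
        self.temperature = temperature
        self.mass = mass
        self.connectivity = connectivity or default_connectivity(k)
        self.structure = structure or build_basic_structure(
            sequence, helical_params, placement
        )
        self.enm: ElasticNetworkModel = build_model(self.structure, self.connectivity, k)
        self.frames: PairFrames = pair_frames(
            self.enm.coords[0::2], self.enm.coords[1::2], bend_projection
        )
        self._hessian: Hessian | None = None

    @classmethod
    def from_sequence(cls, sequence, k: int = 3, **kwargs) -> "DnaElasticNetwork":
        return cls(sequence, k=k, **kwargs)

    @property
    def n_pairs(self) -> int:
        return self.enm.n_pairs

    @property
    def hessian(self) -> Hessian:
        if self._hessian is None:
            self._hessian = build_hessian(self.enm)
        return self._hessian

    def fit(self, engine: str = "auto") -> "NormalModeResults":
        """Run the thermal-fluctuation analysis.

        ``engine``: ``"modes"`` (full eigendecomposition), ``"solver"``
        (sparse pseudoinverse; no mode spectrum) or ``"auto"``.
        """
        n_dof = 3 * self.enm.n_particles
        if engine == "auto":
            engine = "modes" if n_dof <= AUTO_SOLVER_DOF else "solver"
        if engine == "modes":
            source: CovarianceSource = normal_modes(
                self.hessian, mass=self.mass, temperature=self.temperature
            )
            modes = source
        elif engine == "solver":
            source = PseudoinverseCovariance(self.hessian, temperature=self.temperature)
            modes = None
        else:
            raise ValueError(f"unknown engine {engine!r}")
        w = np.arange(0, self.enm.n_particles, 2)
        c = w + 1
        suite = index_suite(source, w, c, self.frames)
        return NormalModeResults(model=self, cov_source=source, modes=modes, indices=suite)


@dataclass
class NormalModeResults:
    """Fluctuation profiles of a fitted model.

    ``indices`` holds raw arrays (see :func:`dnaenm.indices.index_suite`);
    accessors below apply the end trimming used for reporting.
    """

    model: DnaElasticNetwork
    cov_source: CovarianceSource
    modes: NormalModes | None
    indices: dict[str, np.ndarray]
    trim: int = END_TRIM_PAIRS

    @property
    def n_pairs(self) -> int:
        return self.model.n_pairs

    def trimmed_pairs(self) -> np.ndarray:
        return np.arange(self.trim, self.n_pairs - self.trim)

    def trimmed_steps(self) -> np.ndarray:
        return np.arange(self.trim, self.n_pairs - self.trim - 1)

    @property
    def msf(self) -> np.ndarray:
        """Per-particle MSF F^a, shape (n_pairs, 2), untrimmed."""
        return self.indices["a"]

    def correlation(self) -> np.ndarray:
        """Motion-correlation matrix over particles (W0, C0, W1, C1, ...)."""
        return self.indices["corr"]

    def profiles(self, trimmed: bool = True) -> pd.DataFrame:
        """Wide table of all scalar indices per pair.

        Step indices (bend/twist) at row n refer to the step n -> n+1 and
        are NaN where undefined.
        """
        p = self.n_pairs
        k = self.model.k
        df = pd.DataFrame({"pair_index": np.arange(p)})
        df["base_pair_index"] = self.model.enm.base_pair_index
        for name in idx_mod.PARTICLE_INDICES:
            df[f"F_{name}_W"] = self.indices[name][:, 0]
            df[f"F_{name}_C"] = self.indices[name][:, 1]
        for name in idx_mod.PAIR_INDICES:
            df[f"F_{name}"] = self.indices[name]
        for name in idx_mod.STEP_INDICES:
            col = np.full(p, np.nan)
            col[:-1] = self.indices[name]
            df[f"F_{name}"] = col
        if trimmed:
            lo, hi = self.trim, p - self.trim
            df = df.iloc[lo:hi].copy()
            df.loc[df.index[-1], [f"F_{n}" for n in idx_mod.STEP_INDICES]] = np.nan
        return df

    def magnitudes(self) -> dict[str, float]:
        """Trimmed-profile averages <F^.> of every index."""
        sl = self.trimmed_pairs()
        st = self.trimmed_steps()
        out = {}
        for name in idx_mod.PARTICLE_INDICES:
            out[name] = float(self.indices[name][sl].mean())
        for name in idx_mod.PAIR_INDICES:
            out[name] = float(self.indices[name][sl].mean())
        for name in idx_mod.STEP_INDICES:
            out[name] = float(self.indices[name][st].mean())
        return out

    def summary(self) -> str:
        m = self.model
        mag = self.magnitudes()
        lines = [
            "1PkN elastic-network normal-mode analysis",
            "=" * 57,
            f"sequence id         : {m.sequence.id or '(unnamed)'}",
            f"length              : {len(m.sequence)} bp",
            f"coarse-graining k   : {m.k} nt/particle",
            f"particle pairs      : {m.n_pairs} ({m.enm.n_particles} particles)",
            f"spring constant C^k : {m.connectivity.C} kJ/(A^2 mol)",
            f"temperature         : {m.temperature} K",
            f"modes               : "
            + (f"{self.modes.n_modes}" if self.modes is not None else "(solver path)"),
            f"end trim            : {self.trim} particle pairs per end",
            "-" * 57,
            "trimmed profile averages (A^2):",
        ]
        label = {
            "a": "<F^a>  MSF", "b": "<F^b>  along base pair",
            "s": "<F^s>  along chain", "t": "<F^t>  surface normal",
            "Da": "<DF^a> inter-strand", "Db": "<DF^b> inter-strand b",
            "Ds": "<DF^s> inter-strand s", "Dt": "<DF^t> inter-strand t",
            "bend": "<F^bend> local bending", "twist": "<F^twist> local twisting",
        }
        for name, lab in label.items():
            lines.append(f"  {lab:<26}: {mag[name]:.4f}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.profiles().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def spectrum_to_tsv(self, path) -> None:
        if self.modes is None:
            raise ValueError("no mode spectrum: fit with engine='modes'")
        self.modes.spectrum_frame().to_csv(path, sep="\t", index=False)

    def plot_profiles(self, names=("a", "bend", "twist"), ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        sl = self.trimmed_pairs()
        st = self.trimmed_steps()
        for name in names:
            if name in idx_mod.STEP_INDICES:
                ax.plot(st, self.indices[name][st], label=f"F^{name}")
            elif name in idx_mod.PARTICLE_INDICES:
                ax.plot(sl, self.indices[name][sl, 0], label=f"F^{name} (W)")
            else:
                ax.plot(sl, self.indices[name][sl], label=f"F^{name}")
        ax.set_xlabel("particle pair n")
        ax.set_ylabel(r"fluctuation ($\AA^2$)")
        ax.legend()
        return ax
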