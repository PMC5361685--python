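"""Sequence-dependent equilibrium ("basic") structure of B-DNA.

The double helix is rebuilt from dinucleotide base-step parameters
(twist, roll, tilt in degrees; shift, slide, rise in Angstrom) by the
standard mid-step-triad frame propagation: the base-pair frame is
half-twisted/half-bent into the mid-step frame, translated there by
(shift, slide, rise), and half-twisted/half-bent again.  One pseudo-atom
per nucleotide (a C1' proxy) is placed at fixed cylindrical coordinates
in each base-pair frame, so the model resolves both strands while keeping
a single particle per nucleotide.

Frame convention (right-handed): x points from the helix axis toward the
major groove along the pseudo-dyad, y along the long axis of the base
pair, z along the local helix axis.  Roll is rotation about y, tilt about
x, twist about z.
"""

from __future__ import annotations

import io
import itertools
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

STEP_FIELDS = ("twist", "roll", "tilt", "shift", "slide", "rise")
#: intra-base-pair parameters: rotations (deg) then translations (A)
PAIR_FIELDS = ("buckle", "propeller", "opening", "shear", "stretch", "stagger")

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp_step(step: str) -> str:
    return step.translate(_COMP)[::-1]


def _complement_params(p: dict[str, float]) -> dict[str, float]:
    """Step parameters of the reverse-complement step (sign convention)."""
    q = dict(p)
    q["tilt"] = -p["tilt"]
    q["shift"] = -p["shift"]
    return q


@dataclass(frozen=True)
class HelicalParameterSet:
    """Complete table of the 16 dinucleotide base-step parameters.

    ``steps[XY]`` maps a dinucleotide (read 5'->3' on the Watson strand) to
    a dict over :data:`STEP_FIELDS`.  ``intra_pair`` optionally maps the
    Watson base of a pair to intra-pair parameters (:data:`PAIR_FIELDS`);
    it defaults to all-zero, i.e. planar Watson-Crick geometry.
    """

    steps: dict[str, dict[str, float]]
    intra_pair: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        missing = sorted(
            s for s in ("".join(p) for p in itertools.product("ACGT", repeat=2))
            if s not in self.steps
        )
        if missing:
            raise ValueError(f"missing base steps after complementation: {missing}")
        for s, p in self.steps.items():
            comp = self.steps[_revcomp_step(s)]
            expect = _complement_params(p)
            for f in STEP_FIELDS:
                if not math.isclose(comp[f], expect[f], abs_tol=1e-9):
                    raise ValueError(
                        f"steps {s}/{_revcomp_step(s)} violate the "
                        f"reverse-complement sign convention on {f!r}"
                    )

    def step(self, dinuc: str) -> dict[str, float]:
        return self.steps[dinuc.upper()]

    def pair(self, base: str) -> dict[str, float]:
        return self.intra_pair.get(base.upper(), {f: 0.0 for f in PAIR_FIELDS})

    @classmethod
    def ideal_b(cls, twist: float = 36.0, rise: float = 3.4) -> "HelicalParameterSet":
        """Uniform (sequence-independent) ideal-B table: pure twist and rise."""
        p = {"twist": twist, "roll": 0.0, "tilt": 0.0,
             "shift": 0.0, "slide": 0.0, "rise": rise}
        return cls({ "".join(s): dict(p) for s in itertools.product("ACGT", repeat=2)})


def load_helical_parameters(source) -> HelicalParameterSet:
    """Parse a step-parameter table into a validated :class:`HelicalParameterSet`.

    ``source`` is a path, an open text file, or the table text itself.
    Format: whitespace- or comma-delimited, ``#`` comments, and a header
    line ``step twist roll tilt shift slide rise`` (any column order after
    ``step``).  Steps absent from the table are filled in from their
    reverse complement by the sign convention; a step missing even after
    complementation is an error naming the step.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        s = str(source)
        text = Path(s).read_text() if ("\n" not in s and Path(s).exists()) else s
    lines = [ln.split("#", 1)[0].strip() for ln in io.StringIO(text)]
    rows = [(i + 1, ln.replace(",", " ").split()) for i, ln in enumerate(lines) if ln]
    if not rows:
        raise ValueError("empty helical-parameter table")
    header = [c.lower() for c in rows[0][1]]
    if header[0] != "step" or set(STEP_FIELDS) - set(header):
        raise ValueError(
            f"header must name 'step' and all of {STEP_FIELDS}, got {header}"
        )
    cols = {name: j for j, name in enumerate(header)}
    steps: dict[str, dict[str, float]] = {}
    for lineno, toks in rows[1:]:
        if len(toks) != len(header):
            raise ValueError(f"line {lineno}: expected {len(header)} fields, got {len(toks)}")
        name = toks[cols["step"]].upper()
        if len(name) != 2 or set(name) - set("ACGT"):
            raise ValueError(f"line {lineno}: invalid step name {name!r}")
        rec = {}
        for f in STEP_FIELDS:
            tok = toks[cols[f]]
            try:
                rec[f] = float(tok)
            except ValueError:
                raise ValueError(f"line {lineno}: non-numeric value {tok!r} for {f!r}")
        steps[name] = rec
    for name in list(steps):
        rc = _revcomp_step(name)
        if rc not in steps:
            steps[rc] = _complement_params(steps[name])
    return HelicalParameterSet(steps)


def default_helical_parameters() -> HelicalParameterSet:
    """The packaged X-ray crystal (Olson et al.) B-DNA step-parameter set."""
    with resources.files("dnaenm.data").joinpath("olson1998_bdna.tsv").open() as fh:
        return load_helical_parameters(fh)


@dataclass(frozen=True)
class PlacementConfig:
    """Where the per-nucleotide pseudo-atom sits in its base-pair frame.

    ``pair_distance`` is the intra-pair pseudo-atom separation (canonical
    B-DNA C1'-C1' distance) and ``opening_angle`` the angle of each atom
    from the minor-groove side of the pseudo-dyad (x axis), in degrees.
    The atoms sit in the base-pair plane at radius
    ``pair_distance / (2 sin(opening_angle))``.
    """

    pair_distance: float = 10.4
    opening_angle: float = 54.5

    def local_positions(self) -> tuple[np.ndarray, np.ndarray]:
        ang = math.radians(self.opening_angle)
        r = self.pair_distance / (2.0 * math.sin(ang))
        w = np.array([-r * math.cos(ang), r * math.sin(ang), 0.0])
        c = np.array([-r * math.cos(ang), -r * math.sin(ang), 0.0])
        return w, c


@dataclass(frozen=True)
class BasicStructure:
    """Equilibrium pseudo-atom coordinates of a double helix.

    ``coords_w[i]`` / ``coords_c[i]`` are the Watson / Crick pseudo-atom
    positions of base pair ``i`` (Angstrom); ``origins`` and ``frames``
    hold the base-pair frame of each pair (orthonormal columns x, y, z).
    """

    sequence: str
    coords_w: np.ndarray
    coords_c: np.ndarray
    origins: np.ndarray
    frames: np.ndarray
    placement: PlacementConfig

    @property
    def n_pairs(self) -> int:
        return len(self.sequence)

    def particle_coords(self, pair_indices: np.ndarray) -> np.ndarray:
        """Coordinates of both strands' atoms at the given base pairs.

        Returns an array of shape ``(len(pair_indices), 2, 3)`` ordered
        (Watson, Crick) along the second axis.
        """
        return np.stack(
            [self.coords_w[pair_indices], self.coords_c[pair_indices]], axis=1
        )


def _rz(a: float) -> np.ndarray:
    return Rotation.from_euler("z", a).as_matrix()


def _ry(a: float) -> np.ndarray:
    return Rotation.from_euler("y", a).as_matrix()


def _step_transforms(p: dict[str, float]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rotation to the next frame, mid-step rotation, mid-step translation."""
    twist = math.radians(p["twist"])
    roll = math.radians(p["roll"])
    tilt = math.radians(p["tilt"])
    gamma = math.hypot(roll, tilt)
    # phi: azimuth of the bend axis in the x-y plane, measured from the
    # roll axis (y); pure roll -> phi = 0, pure tilt -> phi = pi/2
    phi = math.atan2(tilt, roll) if gamma > 0 else 0.0
    r_step = _rz(twist / 2 - phi) @ _ry(gamma) @ _rz(twist / 2 + phi)
    r_mid = _rz(twist / 2 - phi) @ _ry(gamma / 2) @ _rz(phi)
    t_mid = np.array([p["shift"], p["slide"], p["rise"]])
    return r_step, r_mid, t_mid


def _pair_offsets(
    pairpar: dict[str, float], w_local: np.ndarray, c_local: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Atom positions in the base-pair frame for given intra-pair parameters.

    The two bases are split symmetrically about the pair frame: each base
    frame is the half (de)rotation by (buckle, propeller, opening) --
    applied as a rotation vector on the frame axes (x, y, z) -- and the
    half (de)translation by (shear, stretch, stagger).
    """
    rot = np.radians([pairpar["buckle"], pairpar["propeller"], pairpar["opening"]])
    trans = np.array([pairpar["shear"], pairpar["stretch"], pairpar["stagger"]])
    if not rot.any() and not trans.any():
        return w_local, c_local
    half = Rotation.from_rotvec(rot / 2).as_matrix()
    w = half @ w_local + trans / 2
    c = half.T @ c_local - trans / 2
    return w, c


def build_basic_structure(
    seq,
    params: HelicalParameterSet | None = None,
    placement: PlacementConfig | None = None,
    initial_frame: np.ndarray | None = None,
    initial_origin: np.ndarray | None = None,
) -> BasicStructure:
    """Propagate base-pair frames along the sequence and place pseudo-atoms.

    The first pair frame defaults to the identity at the origin (a global
    rotation/translation may be prepended via ``initial_frame`` /
    ``initial_origin``); each subsequent frame follows from the step
    parameters of the dinucleotide by the mid-step-triad construction.
    Deterministic: identical inputs give bit-identical coordinates.
    """
    bases = seq.bases if hasattr(seq, "bases") else str(seq).upper()
    if hasattr(seq, "require_unambiguous"):
        seq.require_unambiguous()
    elif set(bases) - set("ACGT"):
        raise ValueError("sequence has non-ACGT symbols; resolve ambiguity first")
    n = len(bases)
    if n < 2:
        raise ValueError(f"need at least 2 base pairs to build a structure, got {n}")
    params = params or default_helical_parameters()
    placement = placement or PlacementConfig()
    w_local, c_local = placement.local_positions()

    origins = np.zeros((n, 3))
    frames = np.zeros((n, 3, 3))
    frames[0] = np.eye(3) if initial_frame is None else np.asarray(initial_frame)
    if initial_origin is not None:
        origins[0] = initial_origin
    for i in range(n - 1):
        r_step, r_mid, t_mid = _step_transforms(params.step(bases[i : i + 2]))
        origins[i + 1] = origins[i] + frames[i] @ r_mid @ t_mid
        frames[i + 1] = frames[i] @ r_step

    coords_w = np.empty((n, 3))
    coords_c = np.empty((n, 3))
    for i, b in enumerate(bases):
        w, c = _pair_offsets(params.pair(b), w_local, c_local)
        coords_w[i] = origins[i] + frames[i] @ w
        coords_c[i] = origins[i] + frames[i] @ c
    return BasicStructure(bases, coords_w, coords_c, origins, frames, placement)


_RESNAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}
_COMP_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}


def export_structure(struct: BasicStructure, path) -> None:
    """Write the pseudo-atoms as a PDB file (one C1' proxy per nucleotide).

    Chain A holds the Watson strand, chain B the Crick strand; residue
    numbers are base-pair indices (1-based).
    """
    if struct.n_pairs == 0:
        raise ValueError("refusing to export an empty structure")
    lines = []
    serial = 1
    atom_name = "C1'"
    for chain, coords, base_of in (
        ("A", struct.coords_w, lambda b: b),
        ("B", struct.coords_c, lambda b: _COMP_BASE[b]),
    ):
        for i in range(struct.n_pairs):
            b = base_of(struct.sequence[i])
            x, y, z = coords[i]
            lines.append(
                f"ATOM  {serial:>5} {atom_name:^4} {_RESNAME[b]:>3} {chain}{i + 1:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C"
            )
            serial += 1
        lines.append(f"TER   {serial:>5}      {_RESNAME[b]:>3} {chain}{struct.n_pairs:>4}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
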