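"""Validation of coarse models against the fine-grained 1P1N reference.

The protocol: build the 1PkN and the 1P1N network on the same basic
structure, compute every fluctuation index in the coarse model (F^*) and
-- with the coarse model's frame vectors, at the represented nucleotides,
with step stride k -- in the fine model (G^*), then compare profiles by
Pearson correlation.  Ensembles of random sequences give the mean and
standard deviation of each correlation; an exhaustive survey over the
2^9 binary connection-class combinations identifies the classes that
maximize the agreement.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .helix import HelicalParameterSet, PlacementConfig, build_basic_structure
from .indices import (
    PAIR_INDICES,
    PARTICLE_INDICES,
    STEP_INDICES,
    index_suite,
    pair_frames,
)
from .model import END_TRIM_PAIRS
from .network import (
    ConnectivityTable,
    build_hessian,
    build_model,
    connectivity_1p1n,
    default_connectivity,
)
from .nma import DEFAULT_TEMPERATURE, NormalModes, PseudoinverseCovariance
from .sequence import DnaSequence, random_sequence

#: correlation names reported per comparison
RHO_NAMES = ("a", "b", "s", "t", "Da", "Db", "Ds", "Dt", "bend", "twist", "c")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.std() == 0.0 or y.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class ComparisonReport:
    """Per-sequence agreement between a 1PkN model and its 1P1N reference.

    ``rho`` maps each index name to a Pearson correlation over the
    trimmed profile (NaN when a profile is constant); ``magnitudes_coarse``
    and ``magnitudes_fine`` hold the trimmed averages <F^.> and <G^.>.
    """

    k: int
    length: int
    n_pairs: int
    trim: int
    rho: dict[str, float]
    magnitudes_coarse: dict[str, float]
    magnitudes_fine: dict[str, float]

    def as_series(self) -> pd.Series:
        return pd.Series({f"rho_{n}": self.rho[n] for n in RHO_NAMES})


def compare_models(
    seq,
    k: int = 3,
    table_k: ConnectivityTable | None = None,
    table_1: ConnectivityTable | None = None,
    helical_params: HelicalParameterSet | None = None,
    placement: PlacementConfig | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    trim: int = END_TRIM_PAIRS,
    bend_projection: str = "t",
) -> ComparisonReport:
    """Run the full 1PkN-vs-1P1N comparison on one sequence.

    Both models share the basic structure and the 1PkN frame vectors, so
    every correlation is a pure measure of how well the coarse network
    reproduces the fine network's fluctuation field at the retained
    nucleotides.
    """
    if isinstance(seq, str):
        seq = DnaSequence(seq)
    struct = build_basic_structure(seq, helical_params, placement)
    table_k = table_k or default_connectivity(k)
    table_1 = table_1 or connectivity_1p1n()

    coarse = build_model(struct, table_k, k)
    fine = build_model(struct, table_1, 1)
    p = coarse.n_pairs
    if p - 2 * trim < 3:
        raise ValueError(
            f"only {p} particle pairs: fewer than 3 profile points remain "
            f"after trimming {trim} pairs per end"
        )
    frames = pair_frames(coarse.coords[0::2], coarse.coords[1::2], bend_projection)

    cov_coarse = PseudoinverseCovariance(build_hessian(coarse), temperature)
    cov_fine = PseudoinverseCovariance(build_hessian(fine), temperature)

    w = np.arange(0, coarse.n_particles, 2)
    suite_f = index_suite(cov_coarse, w, w + 1, frames)
    # fine-model particles sitting at the represented nucleotides
    mapped = coarse.base_pair_index
    suite_g = index_suite(cov_fine, 2 * mapped, 2 * mapped + 1, frames)

    sl = np.arange(trim, p - trim)
    st = np.arange(trim, p - trim - 1)
    rho: dict[str, float] = {}
    for name in PARTICLE_INDICES:
        rho[name] = _pearson(suite_f[name][sl], suite_g[name][sl])
    for name in PAIR_INDICES:
        rho[name] = _pearson(suite_f[name][sl], suite_g[name][sl])
    for name in STEP_INDICES:
        rho[name] = _pearson(suite_f[name][st], suite_g[name][st])
    part = np.concatenate([2 * sl, 2 * sl + 1])
    part.sort()
    iu = np.triu_indices(len(part), 1)
    rho["c"] = _pearson(
        suite_f["corr"][np.ix_(part, part)][iu], suite_g["corr"][np.ix_(part, part)][iu]
    )

    def mags(suite):
        out = {n: float(suite[n][sl].mean()) for n in PARTICLE_INDICES + PAIR_INDICES}
        out.update({n: float(suite[n][st].mean()) for n in STEP_INDICES})
        return out

    return ComparisonReport(
        k=k, length=len(seq), n_pairs=p, trim=trim,
        rho=rho, magnitudes_coarse=mags(suite_f), magnitudes_fine=mags(suite_g),
    )


@dataclass(frozen=True)
class EnsembleResult:
    """Ensemble statistics of the comparison correlations.

    ``stats`` has one row per correlation name with columns mean, sd
    (sample convention, ddof=1) and n; per-sequence values are kept in
    ``per_sequence`` for inspection.
    """

    k: int
    length: int
    n_sequences: int
    seed: int | None
    stats: pd.DataFrame
    per_sequence: pd.DataFrame
    n_failed: int = 0

    def to_json_dict(self) -> dict:
        return {
            "k": self.k, "length": self.length, "n_sequences": self.n_sequences,
            "seed": self.seed, "n_failed": self.n_failed,
            "rho": {
                name: {"mean": float(self.stats.loc[name, "mean"]),
                       "sd": float(self.stats.loc[name, "sd"]),
                       "n": int(self.stats.loc[name, "n"])}
                for name in self.stats.index
            },
        }


def ensemble_stats(
    k: int,
    length: int | None = None,
    n_sequences: int = 500,
    rng: np.random.Generator | int | None = None,
    gc: float | None = None,
    **compare_kwargs,
) -> EnsembleResult:
    """Mean and SD of every comparison correlation over random sequences.

    The default length is 50*k bp (50 particle pairs regardless of k);
    bases are uniform-random unless a GC fraction is fixed.  Per-sequence
    failures are logged, excluded and counted.
    """
    if n_sequences < 2:
        raise ValueError("need at least 2 sequences for ensemble statistics")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    length = length or 50 * k
    rows, failed = [], 0
    for j in range(n_sequences):
        seq = random_sequence(length, rng, gc=gc, id=f"rand{j}")
        try:
            rows.append(compare_models(seq, k=k, **compare_kwargs).as_series())
        except (ValueError, np.linalg.LinAlgError):
            failed += 1
    per_seq = pd.DataFrame(rows).reset_index(drop=True)
    stats = pd.DataFrame(
        {
            "mean": per_seq.mean(),
            "sd": per_seq.std(ddof=1),
            "n": per_seq.notna().sum(),
        }
    )
    stats.index = [s.removeprefix("rho_") for s in stats.index]
    return EnsembleResult(
        k=k, length=length, n_sequences=n_sequences,
        seed=seed if isinstance(seed, int) else None,
        stats=stats, per_sequence=per_seq, n_failed=failed,
    )


def _candidate_tables(k: int, C: float) -> list[ConnectivityTable]:
    out = []
    for bits in itertools.product((0, 1), repeat=9):
        intra, cross = bits[:4], bits[4:]
        out.append(ConnectivityTable(k=k, C=C, intra=intra, cross=cross))
    return out


def connectivity_survey(
    k: int,
    length: int | None = None,
    n_sequences: int = 100,
    rng: np.random.Generator | int | None = None,
    objective: str = "a",
    reference_table: ConnectivityTable | None = None,
    C: float | None = None,
    trim: int = END_TRIM_PAIRS,
    temperature: float = DEFAULT_TEMPERATURE,
) -> pd.DataFrame:
    """Exhaustively rank all 2^9 = 512 binary connection-class tables.

    For every candidate table the mean Pearson correlation of the chosen
    objective profile (default the plain MSF, index "a") against a
    reference -- the 1P1N model by default, or the model built from
    ``reference_table`` -- is evaluated over random sequences.
    Disconnected candidates, and graph-connected candidates whose spring
    geometry leaves internal zero modes (mechanically floppy networks),
    are flagged and ranked last.  Ranking is by mean objective; among
    tables within one standard error of the best, sparser tables (fewer
    active classes) are preferred.

    Returns a DataFrame ordered best-first with the nine class flags,
    mean/sd of the objective, and flags ``connected`` / ``rigid`` /
    ``n_classes``.
    """
    if k <= 1:
        raise ValueError("the survey optimizes coarse levels k > 1")
    if objective not in PARTICLE_INDICES + PAIR_INDICES + STEP_INDICES:
        raise ValueError(f"unknown objective index {objective!r}")
    rng = np.random.default_rng(rng)
    length = length or 50 * k
    C = C or (default_connectivity(k).C if k in (3, 4, 9, 13) else 1.0)
    candidates = _candidate_tables(k, C)

    # connectivity is structural: test each candidate once on a small chain
    probe = build_basic_structure(DnaSequence("A" * max(3 * k, length)),
                                  HelicalParameterSet.ideal_b())
    connected = []
    for cand in candidates:
        try:
            build_model(probe, cand, k)
            connected.append(True)
        except ValueError:
            connected.append(False)

    full = ConnectivityTable(k=k, C=C, intra=(1, 1, 1, 1), cross=(1, 1, 1, 1, 1))
    scores: list[list[float]] = [[] for _ in candidates]
    floppy = [False] * len(candidates)
    for j in range(n_sequences):
        seq = random_sequence(length, rng, id=f"survey{j}")
        struct = build_basic_structure(seq)
        # reference profile at the coarse particle positions
        coarse_probe = build_model(struct, full, k)
        p = coarse_probe.n_pairs
        frames = pair_frames(coarse_probe.coords[0::2], coarse_probe.coords[1::2])
        sl = np.arange(trim, p - trim)
        st = np.arange(trim, p - trim - 1)
        window = st if objective in STEP_INDICES else sl

        if reference_table is None:
            fine = build_model(struct, connectivity_1p1n(), 1)
            cov = PseudoinverseCovariance(build_hessian(fine), temperature)
            mapped = coarse_probe.base_pair_index
            ref_suite = index_suite(cov, 2 * mapped, 2 * mapped + 1, frames,
                                    with_correlation=False)
        else:
            ref_model = build_model(struct, reference_table, k)
            cov = PseudoinverseCovariance(build_hessian(ref_model), temperature)
            w = np.arange(0, ref_model.n_particles, 2)
            ref_suite = index_suite(cov, w, w + 1, frames, with_correlation=False)
        ref_profile = ref_suite[objective][window]

        # class-resolved Hessian pieces let each candidate reuse one build
        pieces = _class_hessian_pieces(struct, k, C)
        w = np.arange(0, 2 * p, 2)
        for ci, (cand, ok) in enumerate(zip(candidates, connected)):
            if not ok or floppy[ci]:
                continue
            h = _assemble(pieces, cand)
            try:
                modes = _modes_from_dense(h, temperature)
            except ValueError:
                # graph-connected but mechanically under-constrained:
                # internal zero modes make the thermal ensemble ill-defined
                floppy[ci] = True
                scores[ci] = []
                continue
            suite = index_suite(modes, w, w + 1, frames, with_correlation=False)
            scores[ci].append(_pearson(suite[objective][window], ref_profile))

    rows = []
    for cand, ok, flop, sc in zip(candidates, connected, floppy, scores):
        rec = cand.to_dict()
        rec["connected"] = ok
        rec["rigid"] = ok and not flop
        rec["n_classes"] = cand.on_classes
        rec["mean_rho"] = float(np.mean(sc)) if sc else float("nan")
        rec["sd_rho"] = float(np.std(sc, ddof=1)) if len(sc) > 1 else float("nan")
        rec["n"] = len(sc)
        rows.append(rec)
    df = pd.DataFrame(rows)
    df = df.sort_values(["rigid", "mean_rho"], ascending=[False, False])
    # sparser-table preference within one standard error of the best
    best = df.iloc[0]
    if best["rigid"] and np.isfinite(best["mean_rho"]):
        se = best["sd_rho"] / np.sqrt(max(best["n"], 1))
        near = df[(df["rigid"]) & (df["mean_rho"] >= best["mean_rho"] - se)]
        chosen = near.sort_values(["n_classes", "mean_rho"], ascending=[True, False]).index[0]
        df = pd.concat([df.loc[[chosen]], df.drop(index=chosen)])
    return df.reset_index(drop=True)


def _class_hessian_pieces(struct, k: int, C: float) -> dict[str, np.ndarray]:
    """Dense Hessian contribution of each of the nine connection classes."""
    full = ConnectivityTable(k=k, C=C, intra=(1, 1, 1, 1), cross=(1, 1, 1, 1, 1))
    model = build_model(struct, full, k)
    hess = build_hessian(model)
    pair = model.pair_of_particle
    strand = model.strand_of_particle
    a, b = model.edges[:, 0], model.edges[:, 1]
    dist = np.abs(pair[a] - pair[b])
    same = strand[a] == strand[b]
    labels = np.where(same, "i", "c")
    cls = np.char.add(labels, dist.astype(str))
    n = hess.n_dof
    pieces = {}
    for name in set(cls):
        sel = cls == name
        h = np.zeros((n, n))
        for (ea, eb), blk in zip(model.edges[sel], hess.blocks[sel]):
            sa, sb = slice(3 * ea, 3 * ea + 3), slice(3 * eb, 3 * eb + 3)
            h[sa, sa] += blk
            h[sb, sb] += blk
            h[sa, sb] -= blk
            h[sb, sa] -= blk
        pieces[name] = h
    return pieces


def _assemble(pieces: dict[str, np.ndarray], table: ConnectivityTable) -> np.ndarray:
    n = next(iter(pieces.values())).shape[0]
    h = np.zeros((n, n))
    for d, w in zip((1, 2, 3, 4), table.intra):
        if w and f"i{d}" in pieces:
            h += w * pieces[f"i{d}"]
    for d, w in zip((0, 1, 2, 3, 4), table.cross):
        if w and f"c{d}" in pieces:
            h += w * pieces[f"c{d}"]
    return h


def _modes_from_dense(h: np.ndarray, temperature: float) -> NormalModes:
    w, v = np.linalg.eigh(h)
    wmax = np.abs(w).max()
    keep = np.abs(w) >= 1e-10 * wmax
    if (~keep).sum() != 6:
        raise ValueError("candidate network degenerate")
    return NormalModes(eigenvalues=w[keep], eigenvectors=v[:, keep],
                       temperature=temperature, mass=1.0)


def gc_magnitude_study(
    length: int = 150,
    gc_grid=tuple(np.round(np.arange(0, 1.01, 0.1), 1)),
    n_per_gc: int = 1000,
    rng: np.random.Generator | int | None = None,
    k: int = 3,
    indices=("a", "bend", "twist"),
    **compare_kwargs,
) -> pd.DataFrame:
    """Fluctuation magnitudes vs GC content for coarse and fine models.

    For each GC value, random sequences at that exact GC fraction are
    compared and the trimmed-profile averages <F^.> (coarse) and <G^.>
    (fine reference) are aggregated.  Returns one row per GC value with
    mean and SD of each magnitude.
    """
    if any(not 0 <= g <= 1 for g in gc_grid):
        raise ValueError("gc_grid values must lie in [0, 1]")
    rng = np.random.default_rng(rng)
    rows = []
    for gc in gc_grid:
        mags: dict[str, list[float]] = {}
        for j in range(n_per_gc):
            seq = random_sequence(length, rng, gc=gc, id=f"gc{gc}_{j}")
            rep = compare_models(seq, k=k, **compare_kwargs)
            for name in indices:
                mags.setdefault(f"F_{name}", []).append(rep.magnitudes_coarse[name])
                mags.setdefault(f"G_{name}", []).append(rep.magnitudes_fine[name])
        row = {"gc": gc, "n": n_per_gc}
        for key, vals in mags.items():
            row[f"{key}_mean"] = float(np.mean(vals))
            row[f"{key}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
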