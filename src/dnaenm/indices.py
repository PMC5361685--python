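"""Anisotropic fluctuation indices of particle pairs.

Per particle pair n (one particle on each strand) three unit vectors are
built from the basic structure: the base-pair direction b_n (Watson ->
Crick atom), the chain direction s_n (difference of consecutive pair
centers) and the surface vector t_n = s_n x b_n (normalized).  Every
reported index is a variance or covariance of linear functionals of the
particle displacements and is therefore evaluated exactly from thermal
covariance blocks:

* directional MSFs F^b, F^s, F^t (projections of each particle's motion),
* inter-strand MSFs DF^a and the projected DF^b, DF^s, DF^t,
* local bending F^bend (difference of projected pair-center motions of
  consecutive pairs) and local twisting F^twist (difference of projected
  inter-strand motions of consecutive pairs),
* the pairwise motion-correlation matrix F^c.

The same formulas evaluated on a fine-grained (1P1N) model at the
nucleotides a coarse model represents -- with the coarse model's frame
vectors and a step stride of k -- yield the reference profiles G^* used
for model validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nma import CovarianceSource

#: per-particle directional indices (evaluated on both strands)
PARTICLE_INDICES = ("a", "b", "s", "t")
#: per-pair inter-strand indices
PAIR_INDICES = ("Da", "Db", "Ds", "Dt")
#: per-step (pair n, n+1) indices
STEP_INDICES = ("bend", "twist")


@dataclass(frozen=True)
class PairFrames:
    """Unit vectors b, s, t and bend-projection data per particle pair.

    ``centers`` are the pair midpoints Q_n of the basic structure;
    ``bend_projection`` R_n is the direction onto which pair-center
    displacements are projected in F^bend (the surface vector t_n by
    default; the base-pair direction b_n is the documented alternative).
    """

    b: np.ndarray
    s: np.ndarray
    t: np.ndarray
    centers: np.ndarray
    bend_projection: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.b)

    def angles_bs(self) -> np.ndarray:
        """Angle between b_n and s_n, radians (close to pi/2 on B-DNA)."""
        return np.arccos(np.clip(np.einsum("nd,nd->n", self.b, self.s), -1, 1))


def pair_frames(
    coords_w: np.ndarray, coords_c: np.ndarray, bend_projection: str = "t"
) -> PairFrames:
    """Build the b/s/t frame set from pair coordinates of a basic structure.

    The chain vector of the last pair (which has no successor) is copied
    from its predecessor; reported profiles are end-trimmed, so the copy
    never reaches outputs.
    """
    if len(coords_w) < 2:
        raise ValueError("need at least 2 particle pairs for frames")
    if bend_projection not in ("t", "b"):
        raise ValueError("bend_projection must be 't' or 'b'")
    b = coords_c - coords_w
    nb = np.linalg.norm(b, axis=1, keepdims=True)
    if np.any(nb < 1e-9):
        raise ValueError("coincident strand atoms in a pair")
    b = b / nb
    centers = 0.5 * (coords_w + coords_c)
    s = np.empty_like(b)
    ds = (coords_w[1:] + coords_c[1:]) - (coords_w[:-1] + coords_c[:-1])
    ns = np.linalg.norm(ds, axis=1, keepdims=True)
    if np.any(ns < 1e-9):
        raise ValueError("coincident consecutive pair centers")
    s[:-1] = ds / ns
    s[-1] = s[-2]
    t = np.cross(s, b)
    nt = np.linalg.norm(t, axis=1, keepdims=True)
    if np.any(nt < 1e-9):
        raise ValueError("degenerate frame: s parallel to b")
    t = t / nt
    r = t if bend_projection == "t" else b
    return PairFrames(b=b, s=s, t=t, centers=centers, bend_projection=r)


def _proj(blocks: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """u_n^T M_n v_n for stacks of 3x3 blocks and per-row vectors."""
    return np.einsum("nd,nde,ne->n", u, blocks, v)


def index_suite(
    cov_source: CovarianceSource,
    particles_w: np.ndarray,
    particles_c: np.ndarray,
    frames: PairFrames,
    with_correlation: bool = True,
) -> dict[str, np.ndarray]:
    """Evaluate all fluctuation indices at the given particle pairs.

    ``particles_w`` / ``particles_c`` are the model particle indices of
    the two strands, one entry per pair, matching ``frames``.  For a
    coarse model these are simply its particles; for a fine-grained
    reference they are the particles at the represented nucleotides, so
    consecutive entries are one coarse step (k nucleotides) apart and the
    step indices automatically use the strided definitions.

    Returns arrays keyed by index name: per-particle indices have shape
    (P, 2) (Watson, Crick), inter-strand indices (P,), step indices
    (P - 1,), and ``corr`` the (2P, 2P) motion-correlation matrix over
    particles interleaved (W0, C0, W1, C1, ...).
    """
    particles_w = np.asarray(particles_w)
    particles_c = np.asarray(particles_c)
    p = len(particles_w)
    if p != len(particles_c) or p != frames.n_pairs:
        raise ValueError("particle lists and frames must have one entry per pair")
    inter = np.empty(2 * p, dtype=particles_w.dtype)
    inter[0::2] = particles_w
    inter[1::2] = particles_c
    cov = cov_source.cov_submatrix(inter)
    c6 = cov.reshape(p, 2, 3, p, 2, 3)
    idx = np.arange(p)
    ww = c6[idx, 0, :, idx, 0, :]
    wc = c6[idx, 0, :, idx, 1, :]
    cc = c6[idx, 1, :, idx, 1, :]

    out: dict[str, np.ndarray] = {}
    out["a"] = np.stack([np.trace(ww, axis1=1, axis2=2), np.trace(cc, axis1=1, axis2=2)], axis=1)
    for name, u in (("b", frames.b), ("s", frames.s), ("t", frames.t)):
        out[name] = np.stack([_proj(ww, u, u), _proj(cc, u, u)], axis=1)

    # inter-strand difference delta-q_W - delta-q_C per pair
    d_nn = ww - wc - wc.transpose(0, 2, 1) + cc
    out["Da"] = np.trace(d_nn, axis1=1, axis2=2)
    for name, u in (("Db", frames.b), ("Ds", frames.s), ("Dt", frames.t)):
        out[name] = _proj(d_nn, u, u)

    # step blocks between pairs n+1 and n
    i1, i0 = idx[1:], idx[:-1]
    ww10 = c6[i1, 0, :, i0, 0, :]
    wc10 = c6[i1, 0, :, i0, 1, :]
    cw10 = c6[i1, 1, :, i0, 0, :]
    cc10 = c6[i1, 1, :, i0, 1, :]
    d_10 = ww10 - wc10 - cw10 + cc10
    t1, t0 = frames.t[1:], frames.t[:-1]
    out["twist"] = (
        _proj(d_nn[1:], t1, t1) + _proj(d_nn[:-1], t0, t0) - 2.0 * _proj(d_10, t1, t0)
    )

    # pair centers Q_n = (delta-q_W + delta-q_C) / 2.  Bending is the
    # variance of the difference of projected center motions of
    # consecutive pairs, each on its own frame vector R_n.  Because R
    # rotates with the helix, soft long-wavelength modes contribute
    # through dQ . (R_{n+1} - R_n); the index is therefore not a purely
    # local quantity and its absolute level grows with chain length.
    s_nn = 0.25 * (ww + wc + wc.transpose(0, 2, 1) + cc)
    s_10 = 0.25 * (ww10 + wc10 + cw10 + cc10)
    r1, r0 = frames.bend_projection[1:], frames.bend_projection[:-1]
    out["bend"] = (
        _proj(s_nn[1:], r1, r1) + _proj(s_nn[:-1], r0, r0) - 2.0 * _proj(s_10, r1, r0)
    )

    if with_correlation:
        m = 2 * p
        c4 = cov.reshape(m, 3, m, 3)
        dot = np.einsum("idjd->ij", c4)
        f = np.sqrt(np.diag(dot))
        out["corr"] = dot / np.outer(f, f)
    return out


def reference_index_suite(
    cov_source: CovarianceSource,
    nucleotide_indices: np.ndarray,
    frames: PairFrames,
    **kwargs,
) -> dict[str, np.ndarray]:
    """Fine-grained (1P1N) reference indices G^* at represented nucleotides.

    ``cov_source`` must come from a fine model whose particles are
    flat-indexed ``2 * nucleotide + strand``; the coarse model's frames are
    inherited and the step stride equals the coarse-graining level by
    construction of ``nucleotide_indices``.
    """
    nucleotide_indices = np.asarray(nucleotide_indices)
    return index_suite(
        cov_source, 2 * nucleotide_indices, 2 * nucleotide_indices + 1, frames, **kwargs
    )
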