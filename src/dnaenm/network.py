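"""Elastic networks on the basic structure: 1P1N and 1PkN models.

A 1PkN model of an L-bp duplex keeps one particle per k consecutive
nucleotides on each strand (2*floor(L/k) particles).  Particles interact
through harmonic springs at their basic-structure separations; which
particle pairs are connected is controlled by nine binary connection
classes: intra-strand neighbours n+-1 .. n+-4 and cross-strand partners
n^c, (n+-1)^c .. (n+-4)^c, where n^c is the particle of the same base
pair on the complementary strand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import yaml
from scipy.sparse.csgraph import connected_components

INTRA_OFFSETS = (1, 2, 3, 4)
CROSS_OFFSETS = (0, 1, 2, 3, 4)


@dataclass(frozen=True)
class ConnectivityTable:
    """Connection-class weights B and spring constant C for one level k.

    ``intra[d-1]`` switches the intra-strand class n+-d (d = 1..4) and
    ``cross[d]`` the cross-strand class (n+-d)^c (d = 0..4).  Weights are
    0/1 by default; fractional weights in [0, 1] are admitted only with
    ``allow_fractional=True``.  ``C`` is in kJ/(A^2 mol).
    """

    k: int
    C: float
    intra: tuple[float, float, float, float]
    cross: tuple[float, float, float, float, float]
    allow_fractional: bool = field(default=False, compare=False)

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError(f"spring constant C must be positive, got {self.C}")
        w = (*self.intra, *self.cross)
        if self.allow_fractional:
            if any(not 0.0 <= x <= 1.0 for x in w):
                raise ValueError("fractional weights must lie in [0, 1]")
        elif any(x not in (0, 1, 0.0, 1.0) for x in w):
            raise ValueError(
                "weights must be binary (pass allow_fractional=True to relax)"
            )

    @property
    def on_classes(self) -> int:
        return int(sum(1 for x in (*self.intra, *self.cross) if x))

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "C": self.C,
            "intra_1": self.intra[0], "intra_2": self.intra[1],
            "intra_3": self.intra[2], "intra_4": self.intra[3],
            "cross_0": self.cross[0], "cross_1": self.cross[1],
            "cross_2": self.cross[2], "cross_3": self.cross[3],
            "cross_4": self.cross[4],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConnectivityTable":
        return cls(
            k=int(d["k"]), C=float(d["C"]),
            intra=tuple(float(d[f"intra_{i}"]) for i in (1, 2, 3, 4)),
            cross=tuple(float(d[f"cross_{i}"]) for i in (0, 1, 2, 3, 4)),
        )

    def save(self, path) -> None:
        text = (yaml.safe_dump if str(path).endswith((".yml", ".yaml"))
                else lambda d: json.dumps(d, indent=2))(self.to_dict())
        with open(path, "w") as fh:
            fh.write(text)

    @classmethod
    def load(cls, path) -> "ConnectivityTable":
        with open(path) as fh:
            text = fh.read()
        d = yaml.safe_load(text)
        return cls.from_dict(d)


#: coarse-graining levels with published optimal weights and C^k
DEFAULT_TABLES: dict[int, ConnectivityTable] = {
    1: ConnectivityTable(1, 7.7, (1, 1, 0, 0), (1, 1, 1, 1, 0)),
    3: ConnectivityTable(3, 7.2, (1, 1, 0, 0), (1, 1, 0, 0, 0)),
    4: ConnectivityTable(4, 0.7, (1, 1, 0, 0), (1, 1, 1, 0, 0)),
    9: ConnectivityTable(9, 0.2, (1, 1, 1, 0), (1, 1, 1, 1, 0)),
    13: ConnectivityTable(13, 0.1, (1, 1, 1, 0), (1, 1, 1, 1, 1)),
}


def connectivity_1p1n() -> ConnectivityTable:
    """The fine-grained (one particle per nucleotide) connection table."""
    return DEFAULT_TABLES[1]


def default_connectivity(k: int) -> ConnectivityTable:
    """Published optimal table for k in {1, 3, 4, 9, 13}."""
    try:
        return DEFAULT_TABLES[k]
    except KeyError:
        raise ValueError(
            f"no published connectivity for k={k}; run a connectivity survey "
            f"(validation.connectivity_survey) to determine one"
        ) from None


def coarse_grain_offset(k: int) -> int:
    """Offset k0 placing particle n at nucleotide i = k*n + k0."""
    return (k - 2) // 2 if k % 2 == 0 else (k - 1) // 2


def coarse_grain_map(length: int, k: int) -> np.ndarray:
    """Base-pair (nucleotide) index represented by each particle pair.

    Particle pair n stands for the k base pairs k*n .. k*n + k - 1 and
    sits at nucleotide i = k*n + k0 (same index on both strands).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if length < 3 * k:
        raise ValueError(
            f"sequence of {length} bp too short for k={k}: need at least {3 * k}"
        )
    n_pairs = length // k
    return k * np.arange(n_pairs) + coarse_grain_offset(k)


@dataclass(frozen=True)
class ElasticNetworkModel:
    """A built network: particle coordinates, weighted springs, bookkeeping.

    Particles are flat-indexed ``2*n + strand`` (strand 0 = Watson,
    1 = Crick) for pair index n, which keeps the spring graph banded.
    ``edges`` is an (E, 2) int array of particle pairs (a < b),
    ``rest_lengths`` their basic-structure separations (A), and
    ``stiffness`` the per-edge force constants C * B (kJ/(A^2 mol)).
    Mass is uniform (1 g/mol by convention) and cancels in all
    fluctuation profiles.
    """

    coords: np.ndarray
    edges: np.ndarray
    rest_lengths: np.ndarray
    stiffness: np.ndarray
    k: int
    pair_of_particle: np.ndarray
    strand_of_particle: np.ndarray
    base_pair_index: np.ndarray
    table: ConnectivityTable
    mass: float = 1.0

    @property
    def n_particles(self) -> int:
        return len(self.coords)

    @property
    def n_pairs(self) -> int:
        return self.n_particles // 2

    def particle_index(self, pair: int, strand: int) -> int:
        return 2 * pair + strand

    def degree(self, particle: int) -> int:
        return int(np.sum(self.edges == particle))


def build_model(
    struct,
    table: ConnectivityTable | None = None,
    k: int | None = None,
) -> ElasticNetworkModel:
    """Select particles from a basic structure and wire the spring network.

    Connection classes are clipped at the chain ends (out-of-range
    partners are omitted).  Raises if the resulting network is not a
    single connected component, which would leave extra zero modes.
    """
    if table is None:
        table = default_connectivity(k if k is not None else 3)
    if k is None:
        k = table.k
    elif k != table.k:
        raise ValueError(f"table is for k={table.k}, requested k={k}")
    mapped = coarse_grain_map(struct.n_pairs, k)
    pair_coords = struct.particle_coords(mapped)  # (P, 2, 3)
    n_pairs = len(mapped)
    coords = pair_coords.reshape(-1, 3)

    rows, cols, weights = [], [], []

    def add(a_pair, a_str, b_pair, b_str, w):
        if w == 0 or not (0 <= b_pair < n_pairs):
            return
        a = 2 * a_pair + a_str
        b = 2 * b_pair + b_str
        if a < b:
            rows.append(a)
            cols.append(b)
            weights.append(w)

    for n in range(n_pairs):
        for s in (0, 1):
            for d, w in zip(INTRA_OFFSETS, table.intra):
                add(n, s, n + d, s, w)
            for d, w in zip(CROSS_OFFSETS, table.cross):
                add(n, s, n + d, 1 - s, w)
                if d:
                    add(n, s, n - d, 1 - s, w)

    edges = np.column_stack([rows, cols]).astype(np.int64) if rows else np.empty((0, 2), np.int64)
    if len(edges):
        edges, uniq = np.unique(edges, axis=0, return_index=True)
        weights = np.asarray(weights)[uniq]
    n_particles = 2 * n_pairs
    adj = sp.coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])),
        shape=(n_particles, n_particles),
    )
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp != 1:
        raise ValueError(
            f"spring network is disconnected ({n_comp} components); "
            "the connectivity table is too sparse"
        )
    diffs = coords[edges[:, 0]] - coords[edges[:, 1]]
    rest = np.linalg.norm(diffs, axis=1)
    if np.any(rest < 1e-9):
        raise ValueError("coincident particles produce a zero-length spring")
    return ElasticNetworkModel(
        coords=coords,
        edges=edges,
        rest_lengths=rest,
        stiffness=table.C * np.asarray(weights, dtype=float),
        k=k,
        pair_of_particle=np.repeat(np.arange(n_pairs), 2),
        strand_of_particle=np.tile([0, 1], n_pairs),
        base_pair_index=mapped,
        table=table,
    )


def potential_energy(model: ElasticNetworkModel, q: np.ndarray) -> float:
    """Harmonic network energy of a displaced configuration, kJ/mol."""
    q = np.asarray(q, dtype=float)
    if q.shape != model.coords.shape:
        raise ValueError(f"expected coordinates of shape {model.coords.shape}, got {q.shape}")
    d = np.linalg.norm(q[model.edges[:, 0]] - q[model.edges[:, 1]], axis=1)
    return float(np.sum(0.5 * model.stiffness * (d - model.rest_lengths) ** 2))


@dataclass(frozen=True)
class Hessian:
    """Second derivative of the network energy at the basic structure.

    Because every spring is at its rest length in the reference state,
    each edge (a, b) with unit bond vector u contributes the exact blocks
    +c u u^T to the (a,a) and (b,b) diagonal and -c u u^T off-diagonal
    (the standard anisotropic-network form).  Symmetric PSD with exactly
    six zero modes for a connected three-dimensional network.
    """

    model: ElasticNetworkModel
    blocks: np.ndarray       # (E, 3, 3) edge blocks c * u u^T
    bandwidth: int           # max |a - b| over edges, in particles

    @property
    def n_dof(self) -> int:
        return 3 * self.model.n_particles

    def to_dense(self) -> np.ndarray:
        n = self.n_dof
        h = np.zeros((n, n))
        e = self.model.edges
        for (a, b), blk in zip(e, self.blocks):
            sa, sb = slice(3 * a, 3 * a + 3), slice(3 * b, 3 * b + 3)
            h[sa, sa] += blk
            h[sb, sb] += blk
            h[sa, sb] -= blk
            h[sb, sa] -= blk
        return h

    def to_sparse(self) -> sp.csc_matrix:
        e = self.model.edges
        blk = self.blocks
        n = self.n_dof
        ii, jj, vv = [], [], []
        off = np.arange(3)
        for (a, b), B in zip(e, blk):
            ia = 3 * a + off
            ib = 3 * b + off
            for idx, sgn in (((ia, ia), 1), ((ib, ib), 1), ((ia, ib), -1), ((ib, ia), -1)):
                r, c = np.meshgrid(idx[0], idx[1], indexing="ij")
                ii.append(r.ravel())
                jj.append(c.ravel())
                vv.append(sgn * B.ravel())
        return sp.csc_matrix(
            (np.concatenate(vv), (np.concatenate(ii), np.concatenate(jj))), shape=(n, n)
        )

    def to_banded_lower(self) -> np.ndarray:
        """LAPACK lower-banded storage ab[d, j] = H[j + d, j]."""
        h = self.to_dense()
        bw = 3 * self.bandwidth + 2
        n = self.n_dof
        ab = np.zeros((bw + 1, n))
        for d in range(bw + 1):
            ab[d, : n - d] = np.diagonal(h, offset=-d)
        return ab


def build_hessian(model: ElasticNetworkModel) -> Hessian:
    if np.any(model.rest_lengths < 1e-9):
        raise ValueError("zero-length spring: Hessian undefined")
    u = (model.coords[model.edges[:, 0]] - model.coords[model.edges[:, 1]])
    u /= model.rest_lengths[:, None]
    blocks = model.stiffness[:, None, None] * np.einsum("ei,ej->eij", u, u)
    bandwidth = int(np.max(np.abs(model.edges[:, 0] - model.edges[:, 1]))) if len(model.edges) else 0
    return Hessian(model=model, blocks=blocks, bandwidth=bandwidth)
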