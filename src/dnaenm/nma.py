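"""Normal-mode analysis and thermal covariances of the harmonic network.

In the harmonic approximation the displacement field is a superposition
of normal modes: delta-q(t) = sum_k A_k v_k exp(i w_k t), with
w_k^2 = lambda_k / m and equipartition amplitudes A_k^2 = k_B T / (m w_k^2)
= R T / lambda_k.  All fluctuation statistics reduce to entries of the
thermal covariance matrix R T H^+ (Moore-Penrose pseudoinverse of the
Hessian), so mass cancels everywhere except mode frequencies.

Two exact, interchangeable evaluation paths are provided:

* :func:`normal_modes` -- full symmetric eigendecomposition; exposes the
  spectrum and eigenvectors (dense or banded storage).
* :class:`PseudoinverseCovariance` -- selected columns of R T H^+ via a
  sparse LU factorization of the saddle system [[H, Rb], [Rb^T, 0]]
  built on the exact rigid-body null space Rb.  For large networks this
  is much cheaper than the full spectrum when only covariances at a
  subset of particles are needed; both paths agree to solver precision.

Units: energies kJ/mol, lengths Angstrom, temperature Kelvin, so
covariances are in A^2 with R = 8.314e-3 kJ/(mol K).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

#: molar gas constant, kJ/(mol K)
R_GAS = 8.314e-3

#: default absolute temperature (K); scales all fluctuation amplitudes
#: uniformly and cancels in every correlation-based comparison
DEFAULT_TEMPERATURE = 300.0

#: eigenvalues below this fraction of the largest count as rigid-body modes
ZERO_MODE_RTOL = 1e-10


class CovarianceSource:
    """Anything that yields thermal covariance blocks R T (H^+)_{ab}."""

    def cov_submatrix(self, particles: np.ndarray) -> np.ndarray:
        """Covariance of the stacked dofs of the given particles.

        Returns a (3m, 3m) matrix ordered like the input particle list.
        """
        raise NotImplementedError


@dataclass(frozen=True)
class NormalModes(CovarianceSource):
    """Nonzero normal modes of a connected elastic network.

    ``eigenvalues`` (ascending, kJ/(A^2 mol)), ``eigenvectors`` with one
    orthonormal column per mode, squared angular frequencies
    ``frequencies_sq = eigenvalues / mass`` and thermal amplitudes
    ``amplitudes_sq = R T / eigenvalues`` (A^2).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    temperature: float
    mass: float

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_particles(self) -> int:
        return self.eigenvectors.shape[0] // 3

    @property
    def frequencies_sq(self) -> np.ndarray:
        return self.eigenvalues / self.mass

    @property
    def amplitudes_sq(self) -> np.ndarray:
        return R_GAS * self.temperature / self.eigenvalues

    def cov_submatrix(self, particles: np.ndarray) -> np.ndarray:
        particles = np.asarray(particles)
        dofs = (3 * particles[:, None] + np.arange(3)).ravel()
        v = self.eigenvectors[dofs]
        return (v * self.amplitudes_sq) @ v.T

    def spectrum_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "mode": np.arange(self.n_modes),
                "eigenvalue": self.eigenvalues,
                "frequency_sq": self.frequencies_sq,
                "amplitude_sq": self.amplitudes_sq,
            }
        )


def _check_zero_modes(w: np.ndarray) -> np.ndarray:
    wmax = np.max(np.abs(w))
    near_zero = np.abs(w) < ZERO_MODE_RTOL * wmax
    n_zero = int(np.sum(near_zero))
    if n_zero > 6:
        raise ValueError(
            f"{n_zero} near-zero eigenvalues: network is disconnected or degenerate"
        )
    if n_zero < 6:
        raise ValueError(
            f"only {n_zero} near-zero eigenvalues; expected the 6 rigid-body modes"
        )
    if np.any(w[~near_zero] < 0):
        raise ValueError(
            "negative eigenvalue beyond tolerance: structure is not at a "
            "potential-energy minimum"
        )
    return ~near_zero


def normal_modes(
    hessian,
    mass: float = 1.0,
    temperature: float = DEFAULT_TEMPERATURE,
    method: str = "auto",
) -> NormalModes:
    """Diagonalize the Hessian and keep the 3N-6 internal modes.

    ``method`` is ``"dense"``, ``"banded"`` (LAPACK symmetric-banded
    solver on the native band structure of the duplex network) or
    ``"auto"``.  Both produce the same spectrum; dense is the default as
    it is faster at the sizes where the full spectrum is worth computing.
    """
    if method not in ("auto", "dense", "banded"):
        raise ValueError(f"unknown method {method!r}")
    if method == "banded":
        ab = hessian.to_banded_lower()
        w, v = sla.eig_banded(ab, lower=True)
    else:
        w, v = np.linalg.eigh(hessian.to_dense())
    keep = _check_zero_modes(w)
    return NormalModes(
        eigenvalues=w[keep],
        eigenvectors=v[:, keep],
        temperature=temperature,
        mass=mass,
    )


def msf(modes: CovarianceSource, particles: np.ndarray | None = None) -> np.ndarray:
    """Mean square fluctuation <|delta-q_n|^2> per particle, A^2."""
    if particles is None:
        if not isinstance(modes, NormalModes):
            raise ValueError("particle subset required for a solver-based source")
        particles = np.arange(modes.n_particles)
    particles = np.asarray(particles)
    if isinstance(modes, NormalModes):
        v = modes.eigenvectors.reshape(-1, 3, modes.n_modes)[particles]
        return np.einsum("ndk,k->n", v**2, modes.amplitudes_sq)
    cov = modes.cov_submatrix(particles)
    return np.einsum("ii->i", cov).reshape(-1, 3).sum(axis=1)


def directional_covariance(
    modes: CovarianceSource, a: int, b: int, u: np.ndarray, w: np.ndarray
) -> float:
    """<(delta-q_a . u)(delta-q_b . w)> for unit direction vectors u, w."""
    u = np.asarray(u, float)
    w = np.asarray(w, float)
    for vec in (u, w):
        if abs(np.linalg.norm(vec) - 1.0) > 1e-8:
            raise ValueError("direction vectors must be unit length")
    cov = modes.cov_submatrix(np.array([a, b]))
    return float(u @ cov[0:3, 3:6] @ w)


def motion_correlation(
    modes: CovarianceSource, particles: np.ndarray | None = None
) -> np.ndarray:
    """Normalized motion correlations <dq_n . dq_l> / sqrt(F_n F_l).

    Returns the full pairwise matrix over the given particles (all
    particles for a mode source); the diagonal is exactly 1.
    """
    if particles is None:
        if not isinstance(modes, NormalModes):
            raise ValueError("particle subset required for a solver-based source")
        particles = np.arange(modes.n_particles)
    particles = np.asarray(particles)
    if isinstance(modes, NormalModes):
        amp = modes.amplitudes_sq
        v = modes.eigenvectors.reshape(-1, 3, modes.n_modes)[particles]
        dot = np.einsum("ndk,k,mdk->nm", v, amp, v, optimize=True)
    else:
        cov = modes.cov_submatrix(particles)
        m = len(particles)
        dot = cov.reshape(m, 3, m, 3)
        dot = np.einsum("ndmd->nm", dot)
    f = np.sqrt(np.diag(dot))
    return dot / np.outer(f, f)


def rigid_body_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the six rigid-body displacement fields."""
    n = len(coords)
    rel = coords - coords.mean(axis=0)
    basis = np.zeros((3 * n, 6))
    for d in range(3):
        basis[d::3, d] = 1.0
    for d, (i, j) in enumerate(((1, 2), (2, 0), (0, 1))):
        rot = np.zeros((n, 3))
        rot[:, i] = -rel[:, j]
        rot[:, j] = rel[:, i]
        basis[:, 3 + d] = rot.ravel()
    q, _ = np.linalg.qr(basis)
    return q


class PseudoinverseCovariance(CovarianceSource):
    """Thermal covariances from selected columns of R T H^+.

    Solves the symmetric saddle system  [[H, Rb], [Rb^T, 0]] [x; mu] =
    [b; 0]  with Rb the orthonormal rigid-body basis, whose solution x is
    exactly H^+ b (springs at rest length make the rigid fields exact
    null vectors of H).  One sparse LU factorization serves any number of
    right-hand sides, so extracting covariances at a particle subset
    costs far less than the full spectrum for long chains.
    """

    def __init__(self, hessian, temperature: float = DEFAULT_TEMPERATURE):
        self.temperature = temperature
        h = hessian.to_sparse()
        self.n_dof = h.shape[0]
        rb = rigid_body_basis(hessian.model.coords)
        saddle = sp.bmat(
            [[h, sp.csc_matrix(rb)], [sp.csc_matrix(rb.T), None]], format="csc"
        )
        self._lu = spla.splu(saddle)

    def cov_submatrix(self, particles: np.ndarray) -> np.ndarray:
        particles = np.asarray(particles)
        dofs = (3 * particles[:, None] + np.arange(3)).ravel()
        rhs = np.zeros((self.n_dof + 6, len(dofs)))
        rhs[dofs, np.arange(len(dofs))] = 1.0
        x = self._lu.solve(rhs)[: self.n_dof]
        cov = R_GAS * self.temperature * x[dofs]
        return 0.5 * (cov + cov.T)

    def pair_block_covariances(self, dof_groups: list[np.ndarray]) -> list[np.ndarray]:
        """Covariance submatrices for several small dof groups in one pass.

        Solves each group's columns lazily in chunks; used by the genome
        scanner where thousands of local blocks are needed but the full
        covariance matrix would not fit in memory.
        """
        out = []
        for dofs in dof_groups:
            rhs = np.zeros((self.n_dof + 6, len(dofs)))
            rhs[dofs, np.arange(len(dofs))] = 1.0
            x = self._lu.solve(rhs)[: self.n_dof]
            cov = R_GAS * self.temperature * x[dofs]
            out.append(0.5 * (cov + cov.T))
        return out
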