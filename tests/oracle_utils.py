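"""Shared brute-force oracles for the test suite.

The Boltzmann-sampling oracle draws configurations from the exact thermal
ensemble N(0, R T H^+) -- built here independently via numpy's pinv --
and evaluates every fluctuation index by its literal definition on the
samples.  Analytic values must agree within Monte-Carlo error.
"""

import numpy as np

from dnaenm.indices import index_suite, pair_frames
from dnaenm.network import build_hessian
from dnaenm.nma import R_GAS, normal_modes


def sampling_oracle_check(model, seed: int, n_draw: int = 100_000, temperature: float = 300.0):
    """Assert all indices of ``model`` against direct ensemble sampling.

    Returns the number of index families checked (for reporting).
    """
    h = build_hessian(model).to_dense()
    cov_full = R_GAS * temperature * np.linalg.pinv(h, rcond=1e-8)
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(
        np.zeros(cov_full.shape[0]), cov_full, size=n_draw, method="eigh"
    ).reshape(n_draw, -1, 3)
    dw = draws[:, 0::2, :]
    dc = draws[:, 1::2, :]
    frames = pair_frames(model.coords[0::2], model.coords[1::2])
    modes = normal_modes(build_hessian(model), temperature=temperature)
    w = np.arange(0, model.n_particles, 2)
    suite = index_suite(modes, w, w + 1, frames)

    checked = 0

    def check(name, samples, analytic):
        nonlocal checked
        est = samples.mean(axis=0)
        se = samples.std(axis=0, ddof=1) / np.sqrt(n_draw)
        assert np.all(np.abs(est - analytic) <= 3 * se + 1e-12), name
        checked += 1

    check("a_W", np.sum(dw**2, axis=2), suite["a"][:, 0])
    check("a_C", np.sum(dc**2, axis=2), suite["a"][:, 1])
    for name, u in (("b", frames.b), ("s", frames.s), ("t", frames.t)):
        check(f"{name}_W", np.einsum("knd,nd->kn", dw, u) ** 2, suite[name][:, 0])
        check(f"{name}_C", np.einsum("knd,nd->kn", dc, u) ** 2, suite[name][:, 1])
    rel = dw - dc
    check("Da", np.sum(rel**2, axis=2), suite["Da"])
    for name, u in (("Db", frames.b), ("Ds", frames.s), ("Dt", frames.t)):
        check(name, np.einsum("knd,nd->kn", rel, u) ** 2, suite[name])
    tw = (np.einsum("knd,nd->kn", rel[:, 1:], frames.t[1:])
          - np.einsum("knd,nd->kn", rel[:, :-1], frames.t[:-1])) ** 2
    check("twist", tw, suite["twist"])
    q = 0.5 * (dw + dc)
    bd = (np.einsum("knd,nd->kn", q[:, 1:], frames.bend_projection[1:])
          - np.einsum("knd,nd->kn", q[:, :-1], frames.bend_projection[:-1])) ** 2
    check("bend", bd, suite["bend"])

    # motion correlations (ratio statistic; compare at a fixed tolerance)
    dots = np.einsum("kid,kjd->kij", draws, draws).mean(axis=0)
    norm = np.sqrt(np.outer(np.diag(dots), np.diag(dots)))
    assert np.abs(dots / norm - suite["corr"]).max() < 0.02
    checked += 1
    return checked
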