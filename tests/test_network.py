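import numpy as np
import pytest

from dnaenm.network import (
    ConnectivityTable,
    build_hessian,
    build_model,
    coarse_grain_map,
    coarse_grain_offset,
    connectivity_1p1n,
    default_connectivity,
    potential_energy,
)


class TestConnectivityTables:
    def test_fine_grained_partner_classes(self):
        """Interior particle: 4 intra-strand + 7 cross-strand = 11 partners."""
        t = connectivity_1p1n()
        assert t.C == pytest.approx(7.7)
        n_intra = 2 * sum(t.intra)
        n_cross = t.cross[0] + 2 * sum(t.cross[1:])
        assert (n_intra, n_cross) == (4, 7)

    @pytest.mark.parametrize(
        "k,C,intra,cross",
        [
            (1, 7.7, (1, 1, 0, 0), (1, 1, 1, 1, 0)),
            (3, 7.2, (1, 1, 0, 0), (1, 1, 0, 0, 0)),
            (4, 0.7, (1, 1, 0, 0), (1, 1, 1, 0, 0)),
            (9, 0.2, (1, 1, 1, 0), (1, 1, 1, 1, 0)),
            (13, 0.1, (1, 1, 1, 0), (1, 1, 1, 1, 1)),
        ],
    )
    def test_published_levels(self, k, C, intra, cross):
        t = default_connectivity(k)
        assert (t.C, t.intra, t.cross) == (C, intra, cross)

    def test_unsupported_level_suggests_survey(self):
        with pytest.raises(ValueError, match="survey"):
            default_connectivity(7)

    def test_binary_enforced_unless_flagged(self):
        with pytest.raises(ValueError, match="binary"):
            ConnectivityTable(3, 7.2, (0.5, 1, 0, 0), (1, 1, 0, 0, 0))
        t = ConnectivityTable(3, 7.2, (0.5, 1, 0, 0), (1, 1, 0, 0, 0),
                              allow_fractional=True)
        assert t.intra[0] == 0.5

    def test_serialization_roundtrip(self, tmp_path):
        for ext in ("json", "yaml"):
            p = tmp_path / f"t.{ext}"
            default_connectivity(9).save(p)
            assert ConnectivityTable.load(p) == default_connectivity(9)


class TestCoarseGrainMap:
    @pytest.mark.parametrize("k,k0", [(1, 0), (3, 1), (4, 1), (5, 2), (9, 4), (13, 6)])
    def test_anchor_offset(self, k, k0):
        assert coarse_grain_offset(k) == k0

    def test_150bp_at_k3_gives_50_pairs(self):
        m = coarse_grain_map(150, 3)
        assert len(m) == 50
        assert m[0] == 1 and m[-1] == 148

    def test_injective_and_in_range(self):
        m = coarse_grain_map(100, 4)
        assert len(np.unique(m)) == len(m)
        assert m.min() >= 0 and m.max() < 100

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            coarse_grain_map(8, 3)


class TestBuildModel:
    def test_particle_count_and_interior_degree(self, crystal_structure_30bp):
        m = build_model(crystal_structure_30bp, connectivity_1p1n(), 1)
        assert m.n_particles == 60
        interior = m.particle_index(15, 0)
        assert m.degree(interior) == 11

    def test_terminal_particle_clipped(self, crystal_structure_30bp):
        m = build_model(crystal_structure_30bp, connectivity_1p1n(), 1)
        # first Watson particle: forward partners only
        first = m.particle_index(0, 0)
        partners = set(m.edges[np.any(m.edges == first, axis=1)].ravel()) - {first}
        pair_of = {p: m.pair_of_particle[p] for p in partners}
        assert all(v >= 0 for v in pair_of.values())
        assert m.degree(first) == 2 + 4  # i+1, i+2 intra; (i..i+3)^c cross

    def test_rest_lengths_match_geometry(self, small_model):
        d = np.linalg.norm(
            small_model.coords[small_model.edges[:, 0]]
            - small_model.coords[small_model.edges[:, 1]],
            axis=1,
        )
        np.testing.assert_array_equal(d, small_model.rest_lengths)

    def test_all_zero_weights_disconnected(self, crystal_structure_30bp):
        dead = ConnectivityTable(1, 7.7, (0, 0, 0, 0), (0, 0, 0, 0, 0))
        with pytest.raises(ValueError, match="disconnected"):
            build_model(crystal_structure_30bp, dead, 1)

    def test_deterministic(self, crystal_structure_30bp):
        a = build_model(crystal_structure_30bp, default_connectivity(3), 3)
        b = build_model(crystal_structure_30bp, default_connectivity(3), 3)
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.edges, b.edges)

    def test_strand_relabel_symmetry(self, small_model):
        """Swapping W and C leaves the edge set invariant."""
        m = small_model
        swapped = {(a ^ 1, b ^ 1) for a, b in map(tuple, m.edges)}
        swapped = {(min(a, b), max(a, b)) for a, b in swapped}
        assert swapped == {tuple(e) for e in m.edges}


class TestPotential:
    def test_zero_at_rest_and_under_rigid_motion(self, tiny_model):
        q0 = tiny_model.coords
        assert potential_energy(tiny_model, q0) == 0.0
        assert potential_energy(tiny_model, q0 + [1.0, -2.0, 0.5]) == pytest.approx(0.0)

    def test_single_edge_closed_form(self):
        """Stretching an isolated spring by delta costs C*B*delta^2/2 exactly."""
        from dnaenm.network import ElasticNetworkModel

        c = 7.2
        coords = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        model = ElasticNetworkModel(
            coords=coords,
            edges=np.array([[0, 1]]),
            rest_lengths=np.array([3.0]),
            stiffness=np.array([c]),
            k=1,
            pair_of_particle=np.array([0, 0]),
            strand_of_particle=np.array([0, 1]),
            base_pair_index=np.array([0]),
            table=default_connectivity(1),
        )
        for delta in (0.1, -0.25, 2.0):
            q = coords.copy()
            q[1, 0] += delta
            assert potential_energy(model, q) == pytest.approx(
                0.5 * c * delta**2, rel=1e-12
            )

    def test_shape_mismatch(self, tiny_model):
        with pytest.raises(ValueError, match="shape"):
            potential_energy(tiny_model, tiny_model.coords[:-1])


class TestHessian:
    def test_symmetric_psd_six_zero_modes(self, small_model):
        h = build_hessian(small_model).to_dense()
        assert np.array_equal(h, h.T)
        w = np.linalg.eigvalsh(h)
        assert np.sum(np.abs(w) < 1e-10 * w.max()) == 6
        assert np.all(w > -1e-10 * w.max())

    def test_translations_exact_rotations_near_null(self, small_model):
        h = build_hessian(small_model).to_dense()
        n = small_model.n_particles
        scale = np.abs(h).max()
        for d in range(3):
            t = np.zeros(3 * n)
            t[d::3] = 1.0
            assert np.abs(h @ t).max() < 1e-12 * scale
        from dnaenm.nma import rigid_body_basis

        rb = rigid_body_basis(small_model.coords)
        hnorm = np.linalg.norm(h)
        for d in range(3, 6):
            assert np.linalg.norm(h @ rb[:, d]) < 1e-8 * hnorm

    def test_linearity_in_spring_constant(self, crystal_structure_30bp):
        t1 = default_connectivity(3)
        t2 = ConnectivityTable(3, 2 * t1.C, t1.intra, t1.cross)
        h1 = build_hessian(build_model(crystal_structure_30bp, t1, 3)).to_dense()
        h2 = build_hessian(build_model(crystal_structure_30bp, t2, 3)).to_dense()
        np.testing.assert_allclose(h2, 2 * h1, atol=1e-12)

    def test_finite_difference_oracle(self):
        """Analytic Hessian matches central differences of the potential."""
        from dnaenm.helix import build_basic_structure
        from dnaenm.sequence import DnaSequence

        struct = build_basic_structure(DnaSequence("ACGTA"))
        model = build_model(struct, connectivity_1p1n(), 1)
        h = build_hessian(model).to_dense()
        n = 3 * model.n_particles
        step = 1e-5
        fd = np.zeros((n, n))
        q0 = model.coords.ravel()

        def v(q):
            return potential_energy(model, q.reshape(-1, 3))

        for i in range(n):
            for j in range(i, n):
                qpp = q0.copy(); qpp[i] += step; qpp[j] += step
                qpm = q0.copy(); qpm[i] += step; qpm[j] -= step
                qmp = q0.copy(); qmp[i] -= step; qmp[j] += step
                qmm = q0.copy(); qmm[i] -= step; qmm[j] -= step
                fd[i, j] = fd[j, i] = (v(qpp) - v(qpm) - v(qmp) + v(qmm)) / (4 * step**2)
        scale = np.abs(h).max()
        assert np.abs(fd - h).max() / scale < 1e-5

    def test_dense_sparse_banded_agree(self, small_model):
        hess = build_hessian(small_model)
        dense = hess.to_dense()
        np.testing.assert_allclose(hess.to_sparse().toarray(), dense, atol=1e-12)
        ab = hess.to_banded_lower()
        for d in range(ab.shape[0]):
            np.testing.assert_allclose(ab[d, : hess.n_dof - d],
                                       np.diagonal(dense, offset=-d), atol=1e-12)
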