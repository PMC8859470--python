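import numpy as np
import pytest

from mpsnet import (
    InterLocalityGraph,
    MPSNParams,
    assemble,
    assign_localities,
    build_intra_locality,
    build_long_distance,
    build_short_range,
    build_template,
    make_lattice,
    sample_interlocality,
    validate_params,
)

from conftest import brute_force_short_range


class TestValidateParams:
    @pytest.mark.parametrize(
        "n,k,s,r",
        [(4096, 16, 16, 2), (144, 9, 4, 1), (16, 4, 4, 1), (1024, 64, 16, 1.5)],
    )
    def test_valid_combinations(self, n, k, s, r):
        assert validate_params(MPSNParams(n=n, r=r, k=k, s=s)).valid

    def test_locality_too_large(self):
        verdict = validate_params(MPSNParams(n=4096, r=1, k=16, s=400))
        assert not verdict.valid
        assert any("locality side 20 exceeds region side 16" in r for r in verdict.reasons)

    def test_parity_violation(self):
        # region side 4 (even) with locality side 3 (odd) cannot be centered
        verdict = validate_params(MPSNParams(n=64, r=1, k=4, s=9))
        assert not verdict.valid
        assert any("parity" in r for r in verdict.reasons)

    def test_all_violations_enumerated(self):
        verdict = validate_params(MPSNParams(n=5, r=-1, k=3, s=2, epsilon=-2))
        assert not verdict.valid
        assert len(verdict.reasons) >= 4

    def test_non_divisible_sides(self):
        verdict = validate_params(MPSNParams(n=144, r=1, k=25, s=1))
        assert not verdict.valid

    def test_probability_clamp(self):
        p = MPSNParams(n=16, r=1, k=4, s=4, epsilon=10)
        assert validate_params(p).valid
        assert p.edge_probability == 1.0


class TestMakeLattice:
    def test_n4(self):
        coords = make_lattice(4)
        assert {tuple(c) for c in coords} == {(0, 0), (0, 1), (1, 0), (1, 1)}

    def test_n144(self):
        coords = make_lattice(144)
        assert coords.shape == (144, 2)
        assert coords.max() == 11

    def test_n4096(self):
        coords = make_lattice(4096)
        assert coords.shape == (4096, 2)
        assert coords.max() == 63

    def test_row_major_bijection(self):
        coords = make_lattice(81)
        ids = coords[:, 0] * 9 + coords[:, 1]
        assert np.array_equal(ids, np.arange(81))

    def test_rejects_non_square(self):
        with pytest.raises(ValueError):
            make_lattice(10)


class TestAssignLocalities:
    def test_disjoint_and_counted(self):
        lm = assign_localities(144, 9, 4)
        all_members = np.concatenate(lm.members)
        assert len(all_members) == 36  # k * s
        assert len(np.unique(all_members)) == 36
        assert all(len(mem) == 4 for mem in lm.members)

    def test_locality_equals_region_when_sides_match(self):
        lm = assign_localities(16, 4, 4)
        # offset 0: locality covers its whole 2x2 region
        assert np.all(lm.locality_of == lm.region_of)

    def test_centered_offset(self):
        # region side 4, locality side 2 -> offset (4-2)/2 = 1 from the corner
        lm = assign_localities(144, 9, 4)
        coords = make_lattice(144)
        locality0 = {tuple(coords[v]) for v in lm.members[0]}
        assert locality0 == {(1, 1), (1, 2), (2, 1), (2, 2)}

    def test_centering_brute_force(self):
        # every locality bounding box is symmetric inside its region
        lm = assign_localities(144, 9, 4)
        coords = make_lattice(144)
        for loc, members in enumerate(lm.members):
            pts = coords[members]
            ri, rj = divmod(loc, 3)
            top, left = ri * 4, rj * 4
            assert pts[:, 0].min() - top == (top + 3) - pts[:, 0].max()
            assert pts[:, 1].min() - left == (left + 3) - pts[:, 1].max()

    def test_members_row_major(self):
        lm = assign_localities(144, 9, 16)
        coords = make_lattice(144)
        for members in lm.members:
            pts = coords[members]
            order = np.lexsort((pts[:, 1], pts[:, 0]))
            assert np.array_equal(order, np.arange(16))


class TestBuildShortRange:
    def test_grid_edge_count(self):
        edges = build_short_range(make_lattice(144), 1)
        assert len(edges) == 264  # 2 * 12 * 11

    def test_r_1_5_includes_diagonals(self):
        edges = build_short_range(make_lattice(9), 1.5)
        assert len(edges) == 20  # 12 orthogonal + 8 diagonal

    def test_below_unit_distance_empty(self):
        assert len(build_short_range(make_lattice(25), 0.5)) == 0

    @pytest.mark.parametrize("r", [1, 1.5, 2, 2.5, 3])
    def test_matches_brute_force(self, r):
        coords = make_lattice(49)
        edges = {tuple(e) for e in build_short_range(coords, r)}
        assert edges == brute_force_short_range(coords, r)

    def test_loop_free_and_canonical(self):
        edges = build_short_range(make_lattice(36), 2)
        assert np.all(edges[:, 0] < edges[:, 1])
        assert len(np.unique(edges, axis=0)) == len(edges)

    def test_rejects_nonpositive_r(self):
        with pytest.raises(ValueError):
            build_short_range(make_lattice(9), 0)


class TestBuildTemplate:
    def test_complete_k4(self):
        t = build_template("complete", 4)
        assert t.n_edges == 6
        a = np.zeros((4, 4))
        a[t.edges[:, 0], t.edges[:, 1]] = 1
        lam = np.linalg.eigvalsh(a + a.T)[-1]
        assert lam == pytest.approx(3.0)

    def test_complete_k16_lambda(self):
        t = build_template("complete", 16)
        a = np.zeros((16, 16))
        a[t.edges[:, 0], t.edges[:, 1]] = 1
        assert np.linalg.eigvalsh(a + a.T)[-1] == pytest.approx(15.0)

    def test_star_16(self):
        t = build_template("star", 16)
        assert t.n_edges == 15
        assert np.all(t.edges[:, 0] == 0)  # hub at row-major index 0

    def test_custom_validated(self):
        t = build_template("custom", 4, edges=[(0, 1), (2, 3)])
        assert t.n_edges == 2
        with pytest.raises(ValueError):
            build_template("custom", 4, edges=[(0, 7)])
        with pytest.raises(ValueError):
            build_template("custom", 4, edges=[(1, 1)])

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            build_template("wheel", 4)


class TestBuildIntraLocality:
    def test_nine_k4_copies(self):
        lm = assign_localities(144, 9, 4)
        edges = build_intra_locality(lm, build_template("complete", 4))
        assert len(edges) == 9 * 6
        # each edge stays within one locality
        loc = lm.locality_of
        assert np.all(loc[edges[:, 0]] == loc[edges[:, 1]])
        assert np.all(loc[edges[:, 0]] >= 0)

    def test_edgeless_template(self):
        lm = assign_localities(144, 9, 4)
        edges = build_intra_locality(lm, build_template("custom", 4, edges=[]))
        assert len(edges) == 0

    def test_size_mismatch(self):
        lm = assign_localities(144, 9, 4)
        with pytest.raises(ValueError):
            build_intra_locality(lm, build_template("complete", 16))


class TestSampleInterlocality:
    def test_epsilon_zero_empty(self):
        assert len(sample_interlocality(16, 0.0, 1).edges) == 0

    def test_clamped_probability_complete(self):
        g = sample_interlocality(4, 10.0, 3)
        assert len(g.edges) == 6  # all C(4,2) pairs present

    def test_deterministic(self):
        a = sample_interlocality(16, 1.0, 42)
        b = sample_interlocality(16, 1.0, 42)
        assert np.array_equal(a.edges, b.edges)

    def test_binomial_mean(self):
        # mean edge count over 200 seeds within 3 sigma of C(64,2)/64
        k, eps = 64, 1.0
        counts = [len(sample_interlocality(k, eps, seed).edges) for seed in range(200)]
        n_pairs = k * (k - 1) // 2
        p = eps / k
        mean, sigma = n_pairs * p, np.sqrt(n_pairs * p * (1 - p) / 200)
        assert abs(np.mean(counts) - mean) < 3 * sigma


class TestBuildLongDistance:
    def test_definitional_complete_bipartite(self, two_locality_pair):
        params, f_ld = two_locality_pair
        lm = assign_localities(params.n, params.k, params.s)
        edges, weights = build_long_distance(lm, f_ld, "definitional")
        assert len(edges) == 16
        assert np.all(weights == 1.0)

    def test_kronecker_excludes_equal_indices(self, two_locality_pair):
        params, f_ld = two_locality_pair
        lm = assign_localities(params.n, params.k, params.s)
        edges, _ = build_long_distance(lm, f_ld, "kronecker")
        assert len(edges) == 12  # s^2 - s

    def test_variants_differ_by_s_per_fld_edge(self):
        lm = assign_localities(144, 9, 4)
        f_ld = InterLocalityGraph.from_edges(9, [(0, 1), (3, 7), (2, 8)])
        e_def, _ = build_long_distance(lm, f_ld, "definitional")
        e_kr, _ = build_long_distance(lm, f_ld, "kronecker")
        assert len(e_def) - len(e_kr) == 4 * 3  # s per inter-locality edge

    def test_empty_fld(self):
        lm = assign_localities(144, 9, 4)
        edges, weights = build_long_distance(lm, InterLocalityGraph.from_edges(9, []))
        assert len(edges) == 0

    def test_ld_edges_cross_localities(self, fig_graph):
        loc = fig_graph.locality_map.locality_of
        e = fig_graph.edges_ld
        if len(e):
            assert np.all(loc[e[:, 0]] != loc[e[:, 1]])
            assert np.all(loc[e[:, 0]] >= 0)
            assert np.all(loc[e[:, 1]] >= 0)

    def test_bad_locality_index(self):
        lm = assign_localities(144, 9, 4)
        with pytest.raises(ValueError):
            build_long_distance(lm, InterLocalityGraph.from_edges(12, [(0, 11)]))


class TestAssemble:
    def test_fig_instance_s_layer_is_grid(self, fig_graph):
        assert len(fig_graph.edges_s) == 264
        assert len(fig_graph.edges_l) == 54

    def test_deterministic(self, fig_params):
        g1 = assemble(fig_params)
        g2 = assemble(fig_params)
        for a, b in [(g1.edges_s, g2.edges_s), (g1.edges_l, g2.edges_l), (g1.edges_ld, g2.edges_ld)]:
            assert np.array_equal(a, b)
        assert np.array_equal(g1.ld_weights, g2.ld_weights)

    def test_layer_counts_match_builders(self, fig_params):
        g = assemble(fig_params)
        coords = make_lattice(fig_params.n)
        assert len(g.edges_s) == len(build_short_range(coords, fig_params.r))

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            assemble(MPSNParams(n=10, r=1, k=4, s=4))

    def test_no_self_loops_any_layer(self, fig_graph):
        for edges in (fig_graph.edges_s, fig_graph.edges_l, fig_graph.edges_ld):
            if len(edges):
                assert np.all(edges[:, 0] != edges[:, 1])
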