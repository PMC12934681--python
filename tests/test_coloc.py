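from itertools import permutations

import numpy as np
import pandas as pd
import pytest

import spatialcoloc as scl
from conftest import make_cells


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def index_count_oracle(graph, labels, index_mask, b):
    """Direct definition: B-labelled contacts of the fixed index cells."""
    count = 0
    for i, j in zip(graph.edge_i, graph.edge_j):
        if index_mask[i] and labels[j] == b:
            count += 1
        if index_mask[j] and labels[i] == b:
            count += 1
    return count


def exhaustive_null(graph, labels, a, b):
    """Exact null mean/variance by enumerating every non-index label
    permutation (uniform over orderings, matching a label shuffle)."""
    labels = np.asarray(labels, dtype=object)
    index_mask = labels == a
    non_index = np.flatnonzero(~index_mask)
    counts = []
    for perm in permutations(labels[non_index]):
        lab = labels.copy()
        lab[non_index] = perm
        counts.append(index_count_oracle(graph, lab, index_mask, b))
    counts = np.array(counts, dtype=float)
    return counts.mean(), counts.var()


def closed_form_mean(graph, labels, a, b):
    """E = M * n_B / N for the non-stratified shuffle."""
    labels = np.asarray(labels, dtype=object)
    index_mask = labels == a
    m = np.zeros(graph.n_cells)
    for i, j in zip(graph.edge_i, graph.edge_j):
        if index_mask[i]:
            m[j] += 1
        if index_mask[j]:
            m[i] += 1
    M = m[~index_mask].sum()
    N = (~index_mask).sum()
    n_b = (labels[~index_mask] == b).sum()
    return M * n_b / N


# ---------------------------------------------------------------------------
# permute_labels
# ---------------------------------------------------------------------------

class TestPermuteLabels:
    def test_all_index_cells_is_identity(self, rng):
        labels = np.array(["A"] * 5, dtype=object)
        out = scl.permute_labels(labels, "A", False, None, rng)
        assert (out == labels).all()

    def test_single_non_index_cell_is_identity(self, rng):
        labels = np.array(["A", "A", "B"], dtype=object)
        out = scl.permute_labels(labels, "A", False, None, rng)
        assert (out == labels).all()

    def test_index_cells_never_move(self, rng):
        labels = np.array(list("AABBCCBC"), dtype=object)
        for _ in range(50):
            out = scl.permute_labels(labels, "A", False, None, rng)
            assert (out[labels == "A"] == "A").all()

    def test_stratified_preserves_each_stratum_multiset(self, rng):
        labels = np.array(list("ABBCC" + "ABCBB"), dtype=object)
        strata = np.array([0] * 5 + [1] * 5)
        for _ in range(100):
            out = scl.permute_labels(labels, "A", True, strata, rng)
            for s in (0, 1):
                got = sorted(out[(strata == s) & (labels != "A")])
                want = sorted(labels[(strata == s) & (labels != "A")])
                assert got == want

    def test_unstratified_shuffle_moves_labels(self, rng):
        labels = np.array(["A"] * 2 + ["B"] * 20 + ["C"] * 20, dtype=object)
        outs = {tuple(scl.permute_labels(labels, "A", False, None, rng))
                for _ in range(20)}
        assert len(outs) > 1


# ---------------------------------------------------------------------------
# coloc_test
# ---------------------------------------------------------------------------

class TestColocTest:
    def test_observed_matches_pair_neighbor_count(self, small_cells):
        g = scl.build_neighbor_graph(small_cells)
        labels = small_cells.labels()
        for a in "ABC":
            for b in "ABC":
                r = scl.coloc_test(g, labels, a, b, scl.PermutationConfig(seed=0))
                assert r.observed == scl.pair_neighbor_count(g, labels, a, b)

    def test_closed_form_null_mean_unstratified(self, small_cells):
        g = scl.build_neighbor_graph(small_cells)
        labels = small_cells.labels()
        cfg = scl.PermutationConfig(seed=1, stratify_by_fov=False, n_permutations=2000)
        r = scl.coloc_test(g, labels, "A", "B", cfg)
        E = closed_form_mean(g, labels, "A", "B")
        se = r.null_sd / np.sqrt(cfg.n_permutations)
        assert abs(r.expected_mean - E) < 3 * se

    def test_exact_enumeration_small_fixture(self):
        df = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(7)],
            "sample_id": "S1", "fov_id": "F1",
            "x_um": [0, 10, 20, 30, 100, 110, 120],
            "y_um": [0.0] * 7,
            "cell_type": list("ABCBACB"),
        })
        cells = scl.CellTable(df)
        g = scl.build_neighbor_graph(cells, radius_um=15.0)
        labels = cells.labels()
        mean_x, var_x = exhaustive_null(g, labels, "A", "B")
        cfg = scl.PermutationConfig(seed=2, stratify_by_fov=False, n_permutations=5000)
        r = scl.coloc_test(g, labels, "A", "B", cfg)
        assert abs(r.expected_mean - mean_x) < 4 * np.sqrt(var_x / cfg.n_permutations)
        assert r.null_sd**2 == pytest.approx(var_x, rel=0.15)

    def test_homotypic_pair_is_degenerate(self, small_cells):
        g = scl.build_neighbor_graph(small_cells)
        r = scl.coloc_test(g, small_cells.labels(), "A", "A", scl.PermutationConfig(seed=0))
        assert r.degenerate and r.p_two_sided == 1.0 and np.isnan(r.z)
        # observed still follows the ordered same-type convention
        assert r.observed == scl.pair_neighbor_count(g, small_cells.labels(), "A", "A")

    def test_absent_neighbor_type_degenerate_p1(self, small_cells):
        g = scl.build_neighbor_graph(small_cells)
        r = scl.coloc_test(g, small_cells.labels(), "A", "Z",
                           scl.PermutationConfig(seed=0),
                           vocabulary=["A", "B", "C", "Z"])
        assert r.observed == 0 and r.degenerate and r.p_two_sided == 1.0

    def test_determinism(self, small_cells):
        g = scl.build_neighbor_graph(small_cells)
        cfg = scl.PermutationConfig(seed=7)
        r1 = scl.coloc_test(g, small_cells.labels(), "A", "B", cfg)
        r2 = scl.coloc_test(g, small_cells.labels(), "A", "B", cfg)
        assert r1 == r2

    def test_empirical_p_mode(self, small_cells):
        g = scl.build_neighbor_graph(small_cells)
        cfg = scl.PermutationConfig(seed=3, p_mode="empirical")
        r = scl.coloc_test(g, small_cells.labels(), "A", "B", cfg)
        assert 0 < r.p_two_sided <= 1
        assert r.p_two_sided >= 2 / (cfg.n_permutations + 1)

    def test_z_sign_matches_observed_minus_expected(self, small_cells):
        g = scl.build_neighbor_graph(small_cells)
        for b in "BC":
            r = scl.coloc_test(g, small_cells.labels(), "A", b,
                               scl.PermutationConfig(seed=4))
            assert np.sign(r.z) == np.sign(r.observed - r.expected_mean)

    def test_n_permutations_floor(self):
        with pytest.raises(scl.ConfigurationError):
            scl.PermutationConfig(n_permutations=10)


# ---------------------------------------------------------------------------
# coloc_all_pairs
# ---------------------------------------------------------------------------

class TestColocAllPairs:
    def test_two_types_give_four_ordered_pairs(self):
        cells = make_cells(n=80, n_types=2, seed=12)
        g = scl.build_neighbor_graph(cells)
        res = scl.coloc_all_pairs(g, cells.labels(), scl.PermutationConfig(seed=0))
        assert len(res) == 4
        assert set(zip(res.index_type, res.neighbor_type)) == {
            ("A", "A"), ("A", "B"), ("B", "A"), ("B", "B")}

    def test_edgeless_graph_all_p1_all_q1(self):
        cells = make_cells(n=30, n_types=2, seed=13)
        g = scl.build_neighbor_graph(cells, radius_um=1e-6)
        assert g.n_edges == 0
        res = scl.coloc_all_pairs(g, cells.labels(), scl.PermutationConfig(seed=0))
        assert (res.p_two_sided == 1.0).all() and (res.q == 1.0).all()

    def test_q_dominates_p_and_is_monotone(self, small_cells):
        g = scl.build_neighbor_graph(small_cells)
        res = scl.coloc_all_pairs(g, small_cells.labels(), scl.PermutationConfig(seed=5))
        assert (res.q >= res.p_two_sided - 1e-12).all()
        by_p = res.sort_values("p_two_sided")
        assert by_p.q.is_monotonic_increasing

    def test_matches_single_pair_test(self, small_cells):
        g = scl.build_neighbor_graph(small_cells)
        cfg = scl.PermutationConfig(seed=6)
        res = scl.coloc_all_pairs(g, small_cells.labels(), cfg)
        single = scl.coloc_test(g, small_cells.labels(), "B", "C", cfg)
        row = res[(res.index_type == "B") & (res.neighbor_type == "C")].iloc[0]
        assert row.observed == single.observed
        assert row.z == pytest.approx(single.z)

    def test_planted_attraction_tops_the_table(self, neutral_spec):
        rel = scl.PairRelation("A", "B", "attract", strength=0.8, offspring_sigma_um=15)
        cells, _ = scl.simulate_cells(neutral_spec(seed=21, density=300, relations=[rel]))
        g = scl.build_neighbor_graph(cells)
        res = scl.coloc_all_pairs(g, cells.labels(), scl.PermutationConfig(seed=0))
        cross = res[res.index_type != res.neighbor_type]
        top2 = cross.nlargest(2, "z")
        assert set(zip(top2.index_type, top2.neighbor_type)) == {("A", "B"), ("B", "A")}

    def test_single_type_errors(self):
        cells = make_cells(n=20, n_types=1, seed=14)
        g = scl.build_neighbor_graph(cells)
        with pytest.raises(scl.ConfigurationError):
            scl.coloc_all_pairs(g, cells.labels())


# ---------------------------------------------------------------------------
# fov_enrichment
# ---------------------------------------------------------------------------

class TestFovEnrichment:
    def test_single_fov_conservation(self):
        cells = make_cells(n=120, n_fovs=1, seed=15)
        g = scl.build_neighbor_graph(cells)
        fmap = scl.fov_enrichment(g, cells.labels(), ("A", "B"),
                                  scl.PermutationConfig(seed=0))
        assert len(fmap) == 1
        assert fmap.observed.iloc[0] == scl.pair_neighbor_count(
            g, cells.labels(), "A", "B")

    def test_per_fov_observed_sums_to_sample_observed(self):
        cells = make_cells(n=300, n_fovs=4, seed=16)
        g = scl.build_neighbor_graph(cells)
        fmap = scl.fov_enrichment(g, cells.labels(), ("A", "C"),
                                  scl.PermutationConfig(seed=0))
        assert fmap.observed.sum() == scl.pair_neighbor_count(
            g, cells.labels(), "A", "C")

    def test_homotypic_pair_scores_zero(self):
        # observed equals the (constant) expectation, so log((o+c)/(e+c)) = 0
        cells = make_cells(n=150, n_fovs=2, seed=17)
        g = scl.build_neighbor_graph(cells)
        fmap = scl.fov_enrichment(g, cells.labels(), ("A", "A"),
                                  scl.PermutationConfig(seed=0))
        ok = fmap[~fmap.flagged]
        assert len(ok) and np.allclose(ok.log_enrichment, 0.0)

    def test_fov_without_index_cells_flagged(self):
        df = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(6)],
            "sample_id": "S1",
            "fov_id": ["F1"] * 3 + ["F2"] * 3,
            "x_um": [0, 10, 20, 0, 10, 20],
            "y_um": 0.0,
            "cell_type": ["A", "B", "B", "B", "B", "C"],
        })
        cells = scl.CellTable(df)
        g = scl.build_neighbor_graph(cells)
        fmap = scl.fov_enrichment(g, cells.labels(), ("A", "B"),
                                  scl.PermutationConfig(seed=0))
        f2 = fmap[fmap.fov_id == "F2"].iloc[0]
        assert f2.flagged and np.isnan(f2.expected_mean)

    def test_log_enrichment_formula(self):
        cells = make_cells(n=200, n_fovs=2, seed=18)
        g = scl.build_neighbor_graph(cells)
        fmap = scl.fov_enrichment(g, cells.labels(), ("B", "C"),
                                  scl.PermutationConfig(seed=1), pseudocount=0.5)
        ok = fmap[~fmap.flagged]
        want = np.log((ok.observed + 0.5) / (ok.expected_mean + 0.5))
        assert np.allclose(ok.log_enrichment, want)

    def test_requires_per_fov_graph(self, neutral_spec):
        cells, _ = scl.simulate_cells(neutral_spec(seed=19, density=100))
        g = scl.build_neighbor_graph(cells, scope="per_sample")
        with pytest.raises(scl.ConfigurationError):
            scl.fov_enrichment(g, cells.labels(), ("A", "B"))
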