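"""Density, density-peaks structures, connection counts and permutation test."""

import numpy as np
import pytest

import pseudospace as ps
from pseudospace.spatial import DISSOCIATIVE


def collinear(n=6, spacing=1.0):
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * spacing
    return coords


class TestNeighborhoodRadius:
    def test_collinear_hand_enumeration(self):
        # 3rd-NN distances for 0..5 spacing 1: (3,2,2,2,2,3) -> median 2
        assert ps.neighborhood_radius(collinear(), nth=3) == pytest.approx(2.0)

    def test_equilateral_triangle_first_neighbor(self):
        coords = np.array([[0, 0], [2, 0], [1, np.sqrt(3)]])
        assert ps.neighborhood_radius(coords, nth=1) == pytest.approx(2.0)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            ps.neighborhood_radius(collinear(3), nth=3)


class TestDensity:
    def test_collinear_hand_count(self):
        np.testing.assert_array_equal(
            ps.density(collinear(), radius=2.0), [2, 3, 4, 4, 3, 2]
        )

    def test_isolated_cell_has_zero(self):
        coords = np.vstack([collinear(3, 0.5), [[100, 0, 0]]])
        assert ps.density(coords, radius=2.0)[-1] == 0

    def test_coincident_points_form_complete_graph(self):
        coords = np.zeros((5, 3))
        np.testing.assert_array_equal(ps.density(coords, radius=1.0), [4] * 5)


class TestDistanceToCenter:
    def test_symmetric_pair_equidistant(self):
        d = ps.distance_to_center(np.array([[-1.0, 0, 0], [1.0, 0, 0]]))
        assert d[0] == d[1] == pytest.approx(1.0)

    def test_single_cell_is_zero(self):
        assert ps.distance_to_center(np.array([[3.0, 4.0, 5.0]]))[0] == 0.0

    def test_unit_square_corners(self):
        corners = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        np.testing.assert_allclose(
            ps.distance_to_center(corners), np.sqrt(2) / 2, atol=1e-12
        )


class TestCompactStructures:
    def test_two_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        blob_a = rng.normal(0, 0.1, size=(20, 3))
        blob_b = rng.normal(0, 0.1, size=(20, 3)) + [50, 0, 0]
        coords = np.vstack([blob_a, blob_b])
        res = ps.find_compact_structures(coords, radius=1.0)
        assert res.n_structures == 2
        labels = np.array(res.structure_labels)
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[20]

    def test_single_blob_single_structure(self):
        rng = np.random.default_rng(1)
        res = ps.find_compact_structures(rng.normal(0, 0.2, (30, 3)), radius=1.0)
        assert res.n_structures == 1
        assert DISSOCIATIVE not in res.structure_labels

    def test_far_outlier_is_dissociative(self):
        rng = np.random.default_rng(2)
        coords = np.vstack([rng.normal(0, 0.1, (20, 3)), [[500, 500, 500]]])
        res = ps.find_compact_structures(coords, radius=1.0)
        assert res.structure_labels[-1] == DISSOCIATIVE
        assert res.density[-1] == 0

    def test_all_coincident_collapse_to_one_structure(self):
        res = ps.find_compact_structures(np.zeros((5, 3)), radius=1.0)
        assert res.n_structures == 1
        assert set(res.structure_labels) == {"S1"}

    def test_global_peak_gets_max_distance_delta(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(0, 0.5, (25, 3))
        res = ps.find_compact_structures(coords, radius=1.0)
        peak = int(np.argmax(res.density))
        from scipy.spatial.distance import pdist

        assert res.delta[peak] == pytest.approx(pdist(coords).max())


class TestCountConnections:
    def test_radius_below_min_distance_gives_zero(self):
        counts = ps.count_connections(collinear(), ["A", "A", "A", "B", "B", "B"], 0.5)
        assert (counts["count"] == 0).all()

    def test_two_by_two_enumeration(self):
        coords = np.array([[0, 0], [0.1, 0], [0, 0.1], [0.1, 0.1]], dtype=float)
        counts = ps.count_connections(coords, ["A", "A", "B", "B"], radius=1.0)
        by_pair = {(r.cluster_a, r.cluster_b): r["count"] for _, r in counts.iterrows()}
        assert by_pair == {("A", "A"): 1, ("B", "B"): 1, ("A", "B"): 4}

    def test_single_cluster_counts_close_pairs(self):
        counts = ps.count_connections(collinear(), ["A"] * 6, radius=1.5)
        assert counts["count"].iloc[0] == 5  # adjacent pairs only

    def test_cutoff_is_strict(self):
        counts = ps.count_connections(collinear(), ["A"] * 6, radius=1.0)
        assert counts["count"].iloc[0] == 0

    def test_invariant_to_cell_relabeling(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(20, 3))
        labels = np.array(list("AB" * 10))
        perm = rng.permutation(20)
        a = ps.count_connections(coords, labels, 1.5)
        b = ps.count_connections(coords[perm], labels[perm], 1.5)
        assert a.equals(b)

    def test_unannotated_cell_rejected(self):
        with pytest.raises(ValueError, match="unannotated"):
            ps.count_connections(collinear(), {"cell0": "A"}, 1.0, cell_ids=[f"cell{i}" for i in range(6)])


def exhaustive_permutation_pvalues(coords, labels, radius):
    """Exact tail probabilities over all distinct label assignments."""
    from itertools import permutations

    labels = list(labels)
    observed = ps.count_connections(coords, labels, radius)
    seen = set()
    null_counts = []
    for perm in permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        null_counts.append(ps.count_connections(coords, list(perm), radius))
    out = {}
    for idx, row in observed.iterrows():
        nulls = np.array([c["count"].iloc[idx] for c in null_counts])
        out[(row.cluster_a, row.cluster_b)] = (
            (nulls >= row["count"]).mean(),
            (nulls <= row["count"]).mean(),
        )
    return out


class TestPermutationTest:
    def test_single_label_degenerate(self):
        report = ps.permutation_test(collinear(), ["A"] * 6, 1.5, n_perm=50, seed=0)
        row = report.table.iloc[0]
        assert row.p_enrich == pytest.approx(1.0)
        assert row.p_deplete == pytest.approx(1.0)
        assert row.call == "other"

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(6, 3))
        labels = ["A", "A", "A", "B", "B", "B"]
        radius = float(np.median(np.linalg.norm(coords[:, None] - coords, axis=2)))
        exact = exhaustive_permutation_pvalues(coords, labels, radius)
        report = ps.permutation_test(coords, labels, radius, n_perm=20000, seed=1)
        for _, row in report.table.iterrows():
            pe, pd_ = exact[(row.cluster_a, row.cluster_b)]
            assert row.p_enrich == pytest.approx(pe, abs=0.02)
            assert row.p_deplete == pytest.approx(pd_, abs=0.02)

    def test_type_one_error_controlled_under_null(self):
        # labels independent of geometry: few pairs should ever be enriched
        rng = np.random.default_rng(10)
        n_enriched = n_pairs = 0
        for _ in range(20):
            coords = rng.normal(size=(60, 3))
            labels = rng.choice(["A", "B", "C"], size=60)
            radius = ps.neighborhood_radius(coords, nth=3)
            report = ps.permutation_test(coords, labels, radius, n_perm=200, seed=int(rng.integers(1 << 30)))
            n_enriched += (report.table.call == "enriched").sum()
            n_pairs += len(report.table)
        assert n_enriched / n_pairs <= 0.10

    def test_invalid_n_perm_rejected(self):
        with pytest.raises(ValueError):
            ps.permutation_test(collinear(), ["A", "B"] * 3, 1.5, n_perm=0)
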