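"""In silico interference: gene edits, depletion, transfer and report diffs."""

import numpy as np
import pytest

import pseudospace as ps
from pseudospace.perturb import PSEUDO_LIGAND, PSEUDO_RECEPTOR, transfer_cells


@pytest.fixture
def annotated_expr():
    return ps.ExpressionMatrix(
        gene_ids=["L", "R", "X"],
        cell_ids=["a1", "a2", "b1"],
        values=np.array([[10.0, 20.0, 0.0], [0.0, 0.0, 30.0], [5.0, 5.0, 5.0]]),
        annotations={"a1": "A", "a2": "A", "b1": "B"},
    )


@pytest.fixture
def simple_lr():
    return ps.LigandReceptorTable(ligands=["L"], receptors=["R"])


class TestGeneEdits:
    def test_knockdown_zeroes_everywhere(self, annotated_expr, simple_lr):
        out, _ = ps.apply_perturbation(
            annotated_expr, simple_lr, ps.PerturbationSpec(kind="knockdown", gene="L")
        )
        np.testing.assert_array_equal(out.values[0], 0.0)
        np.testing.assert_array_equal(out.values[1:], annotated_expr.values[1:])

    def test_overexpress_sets_default_level(self, annotated_expr, simple_lr):
        out, _ = ps.apply_perturbation(
            annotated_expr, simple_lr, ps.PerturbationSpec(kind="overexpress", gene="X")
        )
        np.testing.assert_array_equal(out.values[2], 5000.0)

    def test_cluster_restriction(self, annotated_expr, simple_lr):
        spec = ps.PerturbationSpec(
            kind="overexpress", gene="L", level=100.0, restrict_to_clusters=["A"]
        )
        out, _ = ps.apply_perturbation(annotated_expr, simple_lr, spec)
        np.testing.assert_array_equal(out.values[0], [100.0, 100.0, 0.0])

    def test_unknown_gene_rejected(self, annotated_expr, simple_lr):
        with pytest.raises(KeyError):
            ps.apply_perturbation(
                annotated_expr, simple_lr, ps.PerturbationSpec(kind="knockdown", gene="ZZ")
            )

    def test_knockdown_of_non_lr_gene_leaves_p_unchanged(self, annotated_expr, simple_lr):
        base = ps.affinity_pipeline(annotated_expr, simple_lr, k=2)
        out, lr = ps.apply_perturbation(
            annotated_expr, simple_lr, ps.PerturbationSpec(kind="knockdown", gene="X")
        )
        after = ps.affinity_pipeline(out, lr, k=2)
        np.testing.assert_array_equal(base.p, after.p)


class TestDepletion:
    def test_depleted_cluster_fully_removed(self, annotated_expr, simple_lr):
        out, _ = ps.apply_perturbation(
            annotated_expr, simple_lr, ps.PerturbationSpec(kind="deplete", cluster="A")
        )
        assert out.cell_ids == ["b1"]
        assert set(out.annotations.values()) == {"B"}
        assert out.values.shape == (3, 1)

    def test_unknown_cluster_rejected(self, annotated_expr, simple_lr):
        with pytest.raises(KeyError):
            ps.apply_perturbation(
                annotated_expr, simple_lr, ps.PerturbationSpec(kind="deplete", cluster="Z")
            )


class TestTransfer:
    def _donor(self, n=2):
        return ps.ExpressionMatrix(
            gene_ids=["L", "Y"],
            cell_ids=[f"d{i}" for i in range(n)],
            values=np.full((2, n), 7.0),
        )

    def test_pseudo_pair_wiring(self, annotated_expr, simple_lr):
        combined, lr = transfer_cells(
            annotated_expr, simple_lr, self._donor(), target_cluster="B",
            tcr_level=123.0, pmhc_level=5000.0,
        )
        gi = combined.gene_index()
        pmhc = combined.values[gi[PSEUDO_LIGAND]]
        tcr = combined.values[gi[PSEUDO_RECEPTOR]]
        labels = combined.labels()
        np.testing.assert_array_equal(pmhc[labels == "B"], 5000.0)
        np.testing.assert_array_equal(pmhc[labels != "B"], 0.0)
        np.testing.assert_array_equal(tcr[labels == "transferred"], 123.0)
        np.testing.assert_array_equal(tcr[labels != "transferred"], 0.0)
        assert (lr.ligands[-1], lr.receptors[-1]) == (PSEUDO_LIGAND, PSEUDO_RECEPTOR)
        assert lr.weights[-1] == 1.0

    def test_donor_genes_aligned_and_zero_filled(self, annotated_expr, simple_lr):
        combined, _ = transfer_cells(
            annotated_expr, simple_lr, self._donor(), "B", tcr_level=1.0
        )
        gi = combined.gene_index()
        # host gene absent in donor is zero for donors; donor-only gene zero in host
        np.testing.assert_array_equal(combined.values[gi["X"], 3:], 0.0)
        np.testing.assert_array_equal(combined.values[gi["Y"], :3], 0.0)
        np.testing.assert_array_equal(combined.values[gi["Y"], 3:], 7.0)

    def test_reserved_gene_collision_rejected(self, annotated_expr, simple_lr):
        donor = ps.ExpressionMatrix(
            [PSEUDO_LIGAND], ["d0"], np.array([[1.0]])
        )
        with pytest.raises(ValueError, match="reserved"):
            transfer_cells(annotated_expr, simple_lr, donor, "B", tcr_level=1.0)

    def test_overlapping_cell_ids_rejected(self, annotated_expr, simple_lr):
        donor = ps.ExpressionMatrix(["L"], ["a1"], np.array([[1.0]]))
        with pytest.raises(ValueError, match="collide"):
            transfer_cells(annotated_expr, simple_lr, donor, "B", tcr_level=1.0)

    def test_zero_tcr_level_reproduces_baseline_affinity(self):
        host, lr, _ = ps.generate(ps.tumor_benchmark_spec(seed=0, cells_per_type=15))
        donor = ps.donor_t_cells(10, seed=5)
        combined, lr_aug = transfer_cells(host, lr, donor, "malignant", tcr_level=0.0)
        with_pseudo = ps.compute_affinity(combined, lr_aug).affinity
        without_pseudo = ps.compute_affinity(combined, lr).affinity
        np.testing.assert_array_equal(with_pseudo, without_pseudo)


class TestTransferSweep:
    def test_metrics_bounded_and_shaped(self):
        host, lr, _ = ps.generate(ps.tumor_benchmark_spec(seed=1, cells_per_type=15))
        donor = ps.donor_t_cells(10, seed=2)
        sweep = ps.transfer_sweep(
            host, lr, donor, [0.0, 5000.0], "malignant", seed=0, k=20, max_iter=150
        )
        assert list(sweep.tcr_level) == [0.0, 5000.0]
        for col in ("pct_connections", "pct_infiltrating_T", "pct_targeted_tumor"):
            assert ((sweep[col] >= 0) & (sweep[col] <= 100)).all()
        assert set(sweep.attrs["r2"]) == {
            "pct_connections", "pct_infiltrating_T", "pct_targeted_tumor"
        }

    def test_failing_level_is_identified(self):
        host, lr, _ = ps.generate(ps.tumor_benchmark_spec(seed=1, cells_per_type=15))
        donor = ps.donor_t_cells(10, seed=2)
        with pytest.raises(ValueError, match=">= 0"):
            ps.transfer_sweep(host, lr, donor, [-1.0], "malignant", seed=0)
        with pytest.raises(RuntimeError, match="tcr_level=1.0"):
            ps.transfer_sweep(
                host, lr, donor, [1.0], "missing_cluster", seed=0, k=20, max_iter=50
            )


class TestCompareReports:
    def _report(self, rows):
        import pandas as pd

        table = pd.DataFrame(rows)
        return ps.InteractionReport(
            cluster_names=sorted({r["cluster_a"] for r in rows}),
            table=table, n_perm=10, seed=0, radius=1.0,
        )

    def test_identity_has_zero_deltas(self):
        rows = [
            {"cluster_a": "A", "cluster_b": "B", "count": 5, "call": "enriched"},
            {"cluster_a": "A", "cluster_b": "A", "count": 2, "call": "other"},
        ]
        delta = ps.compare_reports(self._report(rows), self._report(rows))
        assert (delta.count_delta == 0).all()
        assert (delta.transition.str.split("->").str[0] == delta.transition.str.split("->").str[1]).all()

    def test_call_transition_recorded(self):
        before = [{"cluster_a": "A", "cluster_b": "B", "count": 9, "call": "enriched"}]
        after = [{"cluster_a": "A", "cluster_b": "B", "count": 1, "call": "other"}]
        delta = ps.compare_reports(self._report(before), self._report(after))
        assert delta.transition.iloc[0] == "enriched->other"
        assert delta.count_delta.iloc[0] == -8

    def test_depleted_cluster_pairs_flagged_one_sided(self):
        before = [
            {"cluster_a": "A", "cluster_b": "B", "count": 3, "call": "other"},
            {"cluster_a": "B", "cluster_b": "C", "count": 4, "call": "other"},
        ]
        after = [{"cluster_a": "A", "cluster_b": "B", "count": 3, "call": "other"}]
        delta = ps.compare_reports(self._report(before), self._report(after))
        sides = dict(zip(zip(delta.cluster_a, delta.cluster_b), delta.side))
        assert sides[("B", "C")] == "before_only"
        assert sides[("A", "B")] == "both"
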