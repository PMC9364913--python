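"""QC filtering, supervised doublet-cluster detection, and concordance."""

import numpy as np
import pandas as pd
import pytest

from cardiosc import (
    DoubletParams,
    GeneSignature,
    QCThresholds,
    ValidationError,
    apply_qc_filters,
    detect_doublet_clusters,
    doublet_concordance,
    iterative_doublet_removal,
    simulate_dataset,
    SimulationConfig,
)


def _ann_row(modality, n_umi, pct_mito):
    return dict(
        sample_id="s1",
        modality=modality,
        condition="donor",
        sex="male",
        age=50.0,
        cluster="T0",
        n_umi=n_umi,
        pct_mito=pct_mito,
        doublet=False,
    )


def _make(rows):
    import scipy.sparse as sp

    from cardiosc import CountMatrix

    ann = pd.DataFrame(rows, index=[f"c{i}" for i in range(len(rows))])
    counts = CountMatrix(
        sp.csr_matrix(np.ones((2, len(rows)), dtype=int)),
        ["g1", "g2"],
        list(ann.index),
    )
    return counts, ann


class TestQCFilters:
    @pytest.mark.parametrize(
        "modality,n_umi,pct_mito,kept",
        [
            ("cell", 5000, 12.0, False),  # mito at/above 10% removed
            ("cell", 5000, 9.9, True),
            ("cell", 2000, 1.0, False),  # boundary exclusive
            ("cell", 2001, 1.0, True),
            ("cell", 10000, 1.0, False),
            ("nucleus", 1000, 1.0, False),  # boundary exclusive
            ("nucleus", 1001, 1.0, True),
            ("nucleus", 5000, 5.0, False),  # nucleus mito bound is 5%
            ("nucleus", 5000, 4.9, True),
        ],
    )
    def test_strict_bounds(self, modality, n_umi, pct_mito, kept):
        counts, ann = _make([_ann_row(modality, n_umi, pct_mito)])
        out_counts, out_ann = apply_qc_filters(counts, ann)
        assert (out_counts.n_cells == 1) is kept

    def test_all_pass_is_identity(self):
        counts, ann = _make(
            [_ann_row("cell", 5000, 2.0), _ann_row("nucleus", 3000, 1.0)]
        )
        out_counts, out_ann = apply_qc_filters(counts, ann)
        assert out_counts.cell_ids == counts.cell_ids
        assert out_ann.equals(ann)

    def test_idempotent(self, default_dataset):
        counts, ann, _ = default_dataset
        once_c, once_a = apply_qc_filters(counts, ann)
        twice_c, twice_a = apply_qc_filters(once_c, once_a)
        assert twice_c.cell_ids == once_c.cell_ids
        assert twice_a.equals(once_a)

    def test_invalid_thresholds(self):
        with pytest.raises(ValidationError):
            QCThresholds(umi_min_cell=5000, umi_max_cell=2000).validate()


class TestDetectDoubletClusters:
    def _toy_scores_ann(self):
        # cluster B: two signatures above tau and 2x median UMI -> flagged
        scores = pd.DataFrame(
            {
                "sigX": [0.0, 0.0, 0.9, 0.8],
                "sigY": [0.0, 0.1, 0.7, 0.9],
            },
            index=list("abcd"),
        )
        ann = pd.DataFrame(
            {
                "cluster": ["A", "A", "B", "B"],
                "n_umi": [1000, 1000, 3000, 3200],
            },
            index=list("abcd"),
        )
        return scores, ann

    def test_hand_built_two_cluster_toy(self):
        scores, ann = self._toy_scores_ann()
        assert detect_doublet_clusters(scores, ann) == ["B"]

    def test_single_signature_never_flags(self):
        scores, ann = self._toy_scores_ann()
        scores["sigY"] = -1.0  # only one signature high, huge UMI irrelevant
        assert detect_doublet_clusters(scores, ann) == []

    def test_umi_ratio_required(self):
        scores, ann = self._toy_scores_ann()
        ann["n_umi"] = 1000  # co-expression alone is not enough
        assert detect_doublet_clusters(scores, ann) == []

    def test_needs_two_signatures(self):
        scores, ann = self._toy_scores_ann()
        with pytest.raises(ValidationError, match="2 population signatures"):
            detect_doublet_clusters(scores[["sigX"]], ann)

    def test_label_renaming_and_order_invariance(self):
        scores, ann = self._toy_scores_ann()
        renamed = ann.copy()
        renamed["cluster"] = renamed["cluster"].map({"A": "z9", "B": "k2"})
        assert detect_doublet_clusters(scores, renamed) == ["k2"]
        perm = np.array([2, 0, 3, 1])
        assert (
            detect_doublet_clusters(scores.iloc[perm], ann.iloc[perm]) == ["B"]
        )


class TestIterativeRemoval:
    def test_clean_data_untouched(self):
        cfg = SimulationConfig(
            seed=2,
            n_samples_donor=4,
            n_samples_dcm=3,
            cells_per_sample=120,
            n_genes=400,
            doublet_rate=0.0,
        )
        counts, ann, truth = simulate_dataset(cfg)
        sigs = [GeneSignature(t, g) for t, g in truth.markers.items()]
        out_counts, out_ann, report = iterative_doublet_removal(counts, ann, sigs)
        assert report.iterations == 0
        assert out_counts.cell_ids == counts.cell_ids
        assert not report.doublet_flag.any()

    def test_planted_doublets_removed(self):
        """Doublet clusters planted at the default 5% rate are fully removed
        within the modality's iteration budget."""
        cfg = SimulationConfig(seed=5)
        counts, ann, truth = simulate_dataset(cfg)
        counts, ann = apply_qc_filters(counts, ann)
        sigs = [GeneSignature(t, g) for t, g in truth.markers.items()]
        for modality, max_it in (("nucleus", 3), ("cell", 2)):
            mask = (ann["modality"] == modality).to_numpy()
            sub_c, sub_a = counts.subset_cells(mask), ann.loc[mask]
            out_c, out_a, report = iterative_doublet_removal(
                sub_c, sub_a, sigs, DoubletParams(max_iterations=max_it)
            )
            assert report.iterations <= max_it
            assert out_a["doublet"].sum() == 0
            # no singlet cluster was flagged
            flagged = {c for it in report.flagged_per_iteration for c in it}
            assert all(c.startswith("doublet:") for c in flagged)

    def test_report_iterations_bounded(self, small_dataset):
        counts, ann, truth = small_dataset
        sigs = [GeneSignature(t, g) for t, g in truth.markers.items()]
        params = DoubletParams(max_iterations=1)
        _, _, report = iterative_doublet_removal(counts, ann, sigs, params)
        assert report.iterations <= 1


class TestConcordance:
    def test_hand_vector(self):
        flags = np.array([True, True, False, False, False, False])
        scores = np.array([0.3, 0.1, 0.1, 0.1, 0.3, 0.1])
        assert doublet_concordance(flags, scores, 0.2) == (0.5, 0.75)

    def test_perfect_agreement(self):
        scores = np.array([0.5, 0.1, 0.9, 0.05])
        flags = scores > 0.2
        assert doublet_concordance(flags, scores, 0.2) == (1.0, 1.0)

    def test_disjoint_flags(self):
        scores = np.array([0.5, 0.1, 0.9, 0.05])
        flags = ~(scores > 0.2)
        dbl, ret = doublet_concordance(flags, scores, 0.2)
        assert dbl == 0.0
        assert ret == 0.0  # every retained cell has a high score here

    def test_empty_flag_set_warns_nan(self, caplog):
        flags = np.zeros(4, dtype=bool)
        scores = np.array([0.1, 0.1, 0.3, 0.1])
        dbl, ret = doublet_concordance(flags, scores, 0.2)
        assert np.isnan(dbl)
        assert ret == 0.75

    def test_length_mismatch(self):
        with pytest.raises(ValidationError, match="length"):
            doublet_concordance(np.array([True]), np.array([0.1, 0.2]))

    def test_synthetic_flags_vs_external_score(self):
        """Flags from the supervised procedure agree with a synthetic
        external score built from ground truth plus noise."""
        cfg = SimulationConfig(seed=9, n_samples_donor=6, n_samples_dcm=4,
                               cells_per_sample=150, n_genes=600)
        counts, ann, truth = simulate_dataset(cfg)
        counts, ann = apply_qc_filters(counts, ann)
        sigs = [GeneSignature(t, g) for t, g in truth.markers.items()]
        mask = (ann["modality"] == "nucleus").to_numpy()
        sub_c, sub_a = counts.subset_cells(mask), ann.loc[mask]
        _, _, report = iterative_doublet_removal(sub_c, sub_a, sigs)
        rng = np.random.default_rng(0)
        truth_flags = truth.true_doublet.reindex(report.doublet_flag.index)
        external = np.where(
            truth_flags, 0.4, 0.05
        ) + rng.uniform(0, 0.05, size=len(truth_flags))
        dbl, ret = doublet_concordance(
            report.doublet_flag.to_numpy(), external, 0.2
        )
        assert dbl > 0.9
        assert ret > 0.9
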