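"""Feature aggregation, direction of change, overlap, hub identification."""
import dataclasses

import numpy as np
import pytest

import brainmkl as bm
from brainmkl.exceptions import CompatibilityError, ConfigError, InputError
from brainmkl.pipeline import CVResult, ExperimentConfig, FoldRecord
from brainmkl.reporting import (
    aggregate_features, direction_of_change, identify_hubs, nodal_strength,
    overlap_analysis,
)


def _toy_cv_result(selections, modality="functional", n_subjects=6):
    """Hand-built CV result with the given per-fold edge selections."""
    folds = [
        FoldRecord(
            test_indices=np.array([i % n_subjects]),
            y_true=np.array([1.0]),
            y_pred=np.array([1.0]),
            decision=np.array([0.5]),
            selected_edges={modality: np.asarray(sel, dtype=int)},
            selected_t={modality: np.ones(len(sel))},
            beta=np.array([1.0]),
            C=1.0,
        )
        for i, sel in enumerate(selections)
    ]
    cfg = ExperimentConfig(modalities=(modality,), k_edges=len(selections[0]))
    return CVResult(folds, cfg, tuple(f"s{i}" for i in range(n_subjects)), "patient", "control")


def _toy_dataset(n_regions=5, n_subjects=6, modality="functional", seed=0):
    rng = np.random.default_rng(seed)
    n_edges = n_regions * (n_regions - 1) // 2
    feats = {modality: rng.standard_normal((n_subjects, n_edges))}
    y = np.array([1.0] * (n_subjects // 2) + [-1.0] * (n_subjects - n_subjects // 2))
    from brainmkl.networks import edge_pairs
    return bm.FeatureDataset(
        feats, y, tuple("pc"[int(v < 0)] for v in y),
        tuple(f"s{i}" for i in range(n_subjects)),
        tuple(f"R{i}" for i in range(n_regions)),
        edge_pairs(n_regions), "patient", "control",
    )


class TestAggregateFeatures:
    def test_edge_selected_in_every_fold_has_unit_frequency(self):
        res = _toy_cv_result([[0, 1], [0, 2], [0, 3]])
        rep = aggregate_features(res, _toy_dataset())
        row = rep.table[rep.table.edge_index == 0].iloc[0]
        assert row.frequency == pytest.approx(1.0)

    def test_unselected_edges_absent_from_report(self):
        res = _toy_cv_result([[0, 1], [0, 1]])
        rep = aggregate_features(res, _toy_dataset())
        assert set(rep.table.edge_index) == {0, 1}

    def test_frequency_conservation(self):
        selections = [[0, 1], [1, 2], [2, 3]]
        res = _toy_cv_result(selections)
        rep = aggregate_features(res, _toy_dataset())
        total = rep.table.frequency.sum() * len(selections)
        assert total == pytest.approx(sum(len(s) for s in selections))

    def test_display_flag_limits_to_requested_count(self):
        res = _toy_cv_result([[0, 1, 2, 3], [0, 1, 2, 4]])
        rep = aggregate_features(res, _toy_dataset(), n_display=2)
        assert rep.display_set("functional").shape[0] == 2

    def test_empty_fold_list_rejected(self):
        res = _toy_cv_result([[0]])
        res.folds = []
        with pytest.raises(InputError):
            aggregate_features(res, _toy_dataset())


class TestDirectionOfChange:
    def test_lower_clinical_mean_is_decreased(self):
        X = np.array([[0.2], [0.2], [0.5], [0.5]])
        y = np.array([1, 1, -1, -1])
        dirs, diff = direction_of_change(X, y, np.array([0]))
        assert dirs == ["decreased"]
        assert diff[0] == pytest.approx(-0.3)

    def test_swapping_groups_flips_every_direction(self, rng):
        X = rng.standard_normal((10, 4))
        y = np.array([1] * 5 + [-1] * 5)
        d1, m1 = direction_of_change(X, y, np.arange(4))
        d2, m2 = direction_of_change(X, -y, np.arange(4))
        flip = {"increased": "decreased", "decreased": "increased", "none": "none"}
        assert d2 == [flip[d] for d in d1]
        np.testing.assert_allclose(m2, -m1, atol=1e-12)

    def test_zero_difference_is_explicit_none(self):
        X = np.array([[1.0], [2.0], [1.0], [2.0]])
        y = np.array([1, 1, -1, -1])
        dirs, _ = direction_of_change(X, y, np.array([0]))
        assert dirs == ["none"]

    def test_planted_positive_effect_reported_increased(self):
        """A d=+2 planted anatomical effect must surface as 'increased' in
        the clinical group in nearly every cohort draw."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            spec = bm.CohortSpec(
                group_sizes={"control": 15, "patient": 15}, n_regions=4,
                effect_edges={"anatomical": [((0, 1), 2.0)]},
                n_timepoints=20, n_density_samples=30, seed=seed,
            )
            ds = bm.build_feature_dataset(
                bm.generate_cohort(spec), modalities=("anatomical",)
            )
            from brainmkl.networks import edge_index
            e = edge_index(0, 1, 4)
            dirs, _ = direction_of_change(ds.features["anatomical"], ds.y, np.array([e]))
            hits += dirs[0] == "increased"
        assert hits / n_seeds >= 0.95


class TestOverlapAnalysis:
    def test_identical_reports_fully_overlap_concordantly(self):
        res = _toy_cv_result([[0, 1], [0, 1]])
        ds = _toy_dataset()
        rep = aggregate_features(res, ds)
        ov = overlap_analysis(rep, rep)
        assert set(ov.table.edge_index) == set(rep.table.edge_index)
        assert ov.table.concordant.all()

    def test_disjoint_edge_sets_give_empty_overlap(self):
        ds = _toy_dataset()
        rep_a = aggregate_features(_toy_cv_result([[0, 1]]), ds)
        rep_b = aggregate_features(_toy_cv_result([[2, 3]]), ds)
        ov = overlap_analysis(rep_a, rep_b)
        assert ov.table.empty

    def test_symmetric_in_arguments(self):
        ds = _toy_dataset()
        rep_a = aggregate_features(_toy_cv_result([[0, 1, 2]]), ds)
        rep_b = aggregate_features(_toy_cv_result([[1, 2, 3]]), ds)
        ab = overlap_analysis(rep_a, rep_b)
        ba = overlap_analysis(rep_b, rep_a)
        assert set(ab.table.edge_index) == set(ba.table.edge_index)

    def test_region_table_mismatch_rejected(self):
        rep_a = aggregate_features(_toy_cv_result([[0]]), _toy_dataset())
        ds_b = _toy_dataset()
        ds_b = dataclasses.replace(
            ds_b, region_labels=tuple(f"Z{i}" for i in range(5))
        )
        rep_b = aggregate_features(_toy_cv_result([[0]]), ds_b)
        with pytest.raises(CompatibilityError):
            overlap_analysis(rep_a, rep_b)

    def test_shared_planted_edges_recovered_in_overlap(self, planted_dataset):
        """Two contrasts generated from the same planted functional edges
        must overlap on them at high effect size."""
        ds, spec = planted_dataset
        cfg = ExperimentConfig(modalities=("functional",), seed=0,
                               outer_cv="kfold", n_outer_folds=5)
        res = bm.run_outer_cv(ds, cfg)
        rep_a = aggregate_features(res, ds)
        sibling = dataclasses.replace(spec, seed=spec.seed + 13,
                                      group_sizes={"control": 30, "relative": 30})
        ds_b = bm.build_feature_dataset(bm.generate_cohort(sibling))
        rep_b = aggregate_features(bm.run_outer_cv(ds_b, cfg), ds_b)
        ov = overlap_analysis(rep_a, rep_b)
        from brainmkl.networks import edge_index
        planted = {
            edge_index(i, j, spec.n_regions)
            for (i, j), _ in spec.effect_edges["functional"]
        }
        assert len(planted & set(ov.table.edge_index)) >= len(planted) // 2


class TestHubs:
    def test_star_graph_center_is_top_hub(self):
        w = np.zeros((6, 6))
        w[0, 1:] = w[1:, 0] = 1.0
        hubs, strength = identify_hubs(w, fraction=0.2)
        assert hubs[0] == 0
        assert strength[0] == pytest.approx(5.0)

    def test_constant_matrix_ties_resolved_by_index(self):
        w = np.ones((10, 10))
        np.fill_diagonal(w, 0.0)
        hubs, _ = identify_hubs(w, fraction=0.3)
        assert hubs.tolist() == [0, 1, 2]

    def test_strengths_match_bruteforce_row_sums(self, rng):
        w = rng.standard_normal((8, 8))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        s = nodal_strength(w)
        for i in range(8):
            ref = sum(abs(w[i, j]) for j in range(8) if j != i)
            assert s[i] == pytest.approx(ref, abs=1e-12)

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_invalid_fraction_rejected(self, fraction):
        with pytest.raises(ConfigError):
            identify_hubs(np.zeros((4, 4)), fraction)

    def test_asymmetric_matrix_rejected(self):
        w = np.zeros((3, 3))
        w[0, 1] = 1.0
        with pytest.raises(InputError):
            identify_hubs(w, 0.5)
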