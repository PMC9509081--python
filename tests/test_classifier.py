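import json

import numpy as np
import pandas as pd
import pytest

from pclike import (CoverageError, PclClassifierModel, PclLikeClassifier,
                    SimulationConfig, apply_platform_distortion,
                    build_classifier, calibrate_threshold, compute_score,
                    generate_cohort, load_model, load_packaged_model,
                    loocv_select_size, save_model, score_samples,
                    standardize_genes)


def _toy_model(genes, signs, threshold=0.0, stats_sd=None):
    k = len(genes)
    stats = pd.DataFrame({"mean": np.zeros(k),
                          "sd": stats_sd if stats_sd is not None else np.ones(k)},
                         index=pd.Index(genes, name="gene_id"))
    return PclClassifierModel(genes=list(genes), signs=np.asarray(signs, float),
                              weights=np.ones(k), threshold=threshold,
                              train_stats=stats)


class TestComputeScore:
    def test_centered_input_scores_zero(self):
        model = _toy_model(["a", "b", "c"], [1, -1, 1])
        out = compute_score(model, {"a": 0.0, "b": 0.0, "c": 0.0})
        assert out.pcl_score == 0.0

    def test_single_gene_passthrough(self):
        model = _toy_model(["a"], [1])
        assert compute_score(model, {"a": 3.2}).pcl_score == pytest.approx(3.2)

    def test_hand_computed_signed_mean(self):
        model = _toy_model(list("abcde"), [1, 1, -1, 1, -1])
        sample = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0, "e": 5.0}
        # (1 + 2 - 3 + 4 - 5) / 5
        assert compute_score(model, sample).pcl_score == pytest.approx(-0.2)

    def test_standardization_applied(self):
        model = _toy_model(["a", "b"], [1, 1], stats_sd=[2.0, 4.0])
        model.train_stats["mean"] = [1.0, 2.0]
        out = compute_score(model, {"a": 3.0, "b": 10.0})
        # z = ((3-1)/2, (10-2)/4) = (1, 2) -> mean 1.5
        assert out.pcl_score == pytest.approx(1.5)

    def test_missing_genes_skipped_and_counted(self):
        model = _toy_model(list("abcd"), [1, 1, 1, 1])
        out = compute_score(model, {"a": 1.0, "b": 3.0})
        assert (out.n_genes_used, out.n_genes_missing) == (2, 2)
        assert out.pcl_score == pytest.approx(2.0)

    def test_coverage_error_below_half(self):
        model = _toy_model(list("abcd"), [1, 1, 1, 1])
        with pytest.raises(CoverageError):
            compute_score(model, {"a": 1.0})

    def test_inclusive_call_at_threshold(self):
        model = _toy_model(["a"], [1], threshold=3.55)
        assert compute_score(model, {"a": 3.55}).call == "PCL-like"
        assert compute_score(model, {"a": 3.5499999}).call == "not-PCL-like"


class TestCalibrateThreshold:
    def test_toy_minimum(self):
        assert calibrate_threshold([3.55, 4.2, 7.0]) == 3.55

    def test_single_score(self):
        assert calibrate_threshold([2.5]) == 2.5

    def test_equals_brute_force_min(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(4, 2, 50)
        assert calibrate_threshold(scores) == min(scores)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            calibrate_threshold([])


class TestLoocvSelectSize:
    def test_singleton_grid(self, default_cohort):
        k, table = loocv_select_size(default_cohort.expression,
                                     default_cohort.annotation, [15])
        assert k == 15
        assert list(table["k"]) == [15]

    def test_separable_data_picks_smallest_k(self):
        # enormous effect, tiny gene noise: AUC = 1 at every k, so the
        # smallest-k tie-break decides
        cfg = SimulationConfig(seed=6, n_samples=60, n_genes=60,
                               n_signal_genes=20, n_confounded_genes=0,
                               signal_effect=5.0, noise_sd=0.01,
                               ctc_noise_sd=1e-9, ctc_burden_weight=0.0)
        cohort = generate_cohort(cfg)
        k, table = loocv_select_size(cohort.expression, cohort.annotation,
                                     [5, 10, 20])
        assert table["auc"].max() == 1.0
        assert k == 5

    def test_recovers_signal_scale(self):
        cfg = SimulationConfig(seed=13, n_samples=90, n_genes=300,
                               n_signal_genes=20, n_confounded_genes=20,
                               signal_effect=0.8)
        cohort = generate_cohort(cfg)
        k, table = loocv_select_size(cohort.expression, cohort.annotation,
                                     [5, 10, 20, 40, 80])
        assert table.loc[table["k"] == k, "auc"].iloc[0] >= 0.95
        assert k in (5, 10, 20, 40)

    def test_missing_class_raises(self, small_cohort):
        annot = small_cohort.annotation.copy()
        annot["disease_label"] = "NDMM"
        with pytest.raises(ValueError, match="pPCL"):
            loocv_select_size(small_cohort.expression, annot, [5])

    def test_fold_rankings_ignore_labels(self, small_cohort):
        """Re-ranking inside folds never sees the held-out label: permuting
        disease labels leaves every fold's training gene ranking unchanged."""
        annot = small_cohort.annotation
        rng = np.random.default_rng(0)
        shuffled = annot.copy()
        lab = shuffled["disease_label"].to_numpy().copy()
        while (lab == shuffled["disease_label"].to_numpy()).all():
            lab = rng.permutation(lab)
        shuffled["disease_label"] = lab
        if not {"NDMM", "pPCL"} <= set(lab):
            pytest.skip("permutation lost a class")
        _, _, d1 = loocv_select_size(small_cohort.expression, annot, [5],
                                     return_fold_details=True)
        _, _, d2 = loocv_select_size(small_cohort.expression, shuffled, [5],
                                     return_fold_details=True)
        for r1, r2 in zip(d1["fold_rankings"], d2["fold_rankings"]):
            assert list(r1) == list(r2)


class TestBuildClassifier:
    def test_discovery_ppcl_sensitivity_is_total(self, default_cohort):
        model = build_classifier(default_cohort.expression,
                                 default_cohort.annotation)
        scored = score_samples(model, default_cohort.expression)
        ppcl = (default_cohort.annotation["disease_label"] == "pPCL").to_numpy()
        assert (scored.loc[ppcl, "call"] == "PCL-like").all()

    def test_validation_sensitivity(self, default_cohort):
        model = build_classifier(default_cohort.expression,
                                 default_cohort.annotation)
        val = generate_cohort(SimulationConfig(
            **{**default_cohort.config.to_dict(), "seed": 424242,
               "n_samples": 400}), study_id="V")
        scored = score_samples(model, val.expression)
        ppcl = (val.annotation["disease_label"] == "pPCL").to_numpy()
        assert (scored.loc[ppcl, "call"] == "PCL-like").mean() >= 0.9

    def test_rebuild_is_deterministic(self, default_cohort):
        m1 = build_classifier(default_cohort.expression,
                              default_cohort.annotation)
        m2 = build_classifier(default_cohort.expression,
                              default_cohort.annotation)
        assert m1.genes == m2.genes
        assert m1.threshold == m2.threshold
        np.testing.assert_array_equal(m1.signs, m2.signs)

    def test_signs_match_training_betas(self, default_cohort):
        from pclike import rank_genes
        model = build_classifier(default_cohort.expression,
                                 default_cohort.annotation)
        ranking, _ = rank_genes(default_cohort.expression,
                                default_cohort.annotation)
        expected = np.sign(ranking.loc[model.genes, "beta_ctc"])
        np.testing.assert_array_equal(model.signs, expected)

    def test_platform_affine_invariance_of_scores(self, default_cohort):
        model = build_classifier(default_cohort.expression,
                                 default_cohort.annotation)
        base = score_samples(model, default_cohort.expression)
        cfg = SimulationConfig(**{**default_cohort.config.to_dict(),
                                  "platform_noise_sd": 0.0})
        distorted = apply_platform_distortion(default_cohort, cfg)
        _, ref_stats = standardize_genes(distorted)
        redone = score_samples(model, distorted, reference_stats=ref_stats)
        np.testing.assert_allclose(redone["pcl_score"], base["pcl_score"],
                                   atol=1e-12)

    def test_interplatform_score_correlation_with_noise(self, default_cohort):
        model = build_classifier(default_cohort.expression,
                                 default_cohort.annotation)
        base = score_samples(model, default_cohort.expression)
        distorted = apply_platform_distortion(default_cohort)
        _, ref_stats = standardize_genes(distorted)
        redone = score_samples(model, distorted, reference_stats=ref_stats)
        r = np.corrcoef(base["pcl_score"], redone["pcl_score"])[0, 1]
        assert r > 0.9


class TestModelSerialization:
    def test_save_load_round_trip(self, default_cohort, tmp_path):
        model = build_classifier(default_cohort.expression,
                                 default_cohort.annotation)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert back.genes == model.genes
        assert back.threshold == model.threshold
        np.testing.assert_allclose(back.train_stats["mean"],
                                   model.train_stats["mean"])

    def test_packaged_model_counts(self):
        model = load_packaged_model()
        assert model.n_genes == 54
        assert model.threshold == 3.55
        assert model.provenance == "packaged_table2"
        assert model.train_stats is None

    def test_packaged_model_requires_reference_stats(self, toy_matrix):
        model = load_packaged_model()
        with pytest.raises(ValueError, match="reference"):
            score_samples(model, toy_matrix)

    def test_duplicate_gene_fixture_rejected(self, tmp_path):
        payload = {"provenance": "packaged_table2", "threshold": 1.0,
                   "genes": [{"gene_id": "A", "sign": 1, "weight": 1.0},
                             {"gene_id": "A", "sign": 1, "weight": 1.0}]}
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="duplicate"):
            load_model(path)

    def test_monotone_classification_in_score(self):
        model = _toy_model(["a"], [1], threshold=1.0)
        calls = [compute_score(model, {"a": v}).call for v in (0.5, 1.0, 2.0)]
        assert calls == ["not-PCL-like", "PCL-like", "PCL-like"]


class TestSklearnEstimator:
    def test_fit_predict_interface(self, default_cohort):
        X = pd.DataFrame(default_cohort.expression.values.T,
                         index=default_cohort.expression.sample_ids,
                         columns=default_cohort.expression.gene_ids)
        annot = default_cohort.annotation
        clf = PclLikeClassifier(size_grid=(10, 25))
        clf.fit(X, annot["disease_label"],
                ctc_fraction=annot["ctc_fraction"],
                burden_fraction=annot["burden_fraction"])
        assert clf.k_ in (10, 25)
        assert np.isfinite(clf.threshold_)
        scores = clf.decision_function(X)
        preds = clf.predict(X)
        assert scores.shape == (len(X),)
        ppcl = (annot["disease_label"] == "pPCL").to_numpy()
        assert (preds[ppcl] == "PCL-like").all()

    def test_get_set_params_round_trip(self):
        clf = PclLikeClassifier(fdr_cutoff=0.1)
        params = clf.get_params()
        assert params["fdr_cutoff"] == 0.1
        clf.set_params(fdr_cutoff=0.01)
        assert clf.fdr_cutoff == 0.01
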