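"""Forced-core logistic models, add-one scans, evaluation."""

import numpy as np
import pandas as pd
import pytest

import npxpanel as npx
from npxpanel import models
from npxpanel.cohort import NpxMatrix


def _two_group_matrix(values: dict, n0: int, n1: int, ages=None) -> NpxMatrix:
    n = n0 + n1
    ids = [f"S{i:03d}" for i in range(n)]
    meta = pd.DataFrame(index=pd.Index(ids, name="sample_id"))
    meta["category"] = ["benign"] * n0 + ["eoc_II_IV"] * n1
    meta["histology"] = "other"
    meta["age"] = 60.0 if ages is None else ages
    meta["qc_pass"] = True
    return NpxMatrix(meta, pd.DataFrame(values, index=meta.index))


class TestFitLogistic:
    def test_single_predictor_auc_equals_marker_auc(self, rng):
        x = np.concatenate([rng.normal(0, 1, 40), rng.normal(1.2, 1, 60)])
        m = _two_group_matrix({"P": x}, 40, 60)
        y = np.array([0] * 40 + [1] * 60)
        model = npx.fit_logistic(m, y, ["P"])
        assert npx.empirical_auc(model.prob, y) == pytest.approx(
            npx.empirical_auc(x, y), abs=1e-12
        )

    def test_coefficient_recovery(self, rng):
        n = 2000
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        eta = 0.2 + 1.0 * x1 - 0.5 * x2
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
        n1 = int(y.sum())
        order = np.argsort(y, kind="mergesort")
        m = _two_group_matrix(
            {"A": x1[order], "B": x2[order]}, n - n1, n1
        )
        model = npx.fit_logistic(m, y[order], ["A", "B"])
        assert model.coef[0] == pytest.approx(1.0, abs=0.1)
        assert model.coef[1] == pytest.approx(-0.5, abs=0.1)
        assert model.converged and not model.separation_flag

    def test_affine_rescaling_leaves_probabilities(self, rng):
        x = np.concatenate([rng.normal(0, 1, 30), rng.normal(1, 1, 30)])
        y = np.array([0] * 30 + [1] * 30)
        m1 = _two_group_matrix({"P": x, "Q": rng.normal(size=60)}, 30, 30)
        m2 = _two_group_matrix(
            {"P": 1000.0 * x + 7.0, "Q": m1.values["Q"].to_numpy()}, 30, 30
        )
        p1 = npx.fit_logistic(m1, y, ["P", "Q"]).prob
        p2 = npx.fit_logistic(m2, y, ["P", "Q"]).prob
        assert np.abs(p1 - p2).max() < 1e-6

    def test_constant_predictor_dropped(self, rng):
        x = np.concatenate([rng.normal(0, 1, 20), rng.normal(1, 1, 20)])
        m = _two_group_matrix({"P": x, "K": np.full(40, 3.0)}, 20, 20)
        y = np.array([0] * 20 + [1] * 20)
        model = npx.fit_logistic(m, y, ["P", "K"])
        assert model.dropped_predictors == ["K"]
        assert model.predictors == ["P"]

    def test_empty_predictor_list_rejected(self, clean_cohort):
        _, y = npx.make_contrast(clean_cohort, npx.BENIGN_VS_CANCER)
        sub, y = npx.make_contrast(clean_cohort, npx.BENIGN_VS_CANCER)
        with pytest.raises(ValueError):
            npx.fit_logistic(sub, y, [])

    def test_separation_flagged_but_scores_usable(self):
        x = np.array([0, 1, 2, 3, 10, 11, 12, 13.0])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        m = _two_group_matrix({"P": x}, 4, 4)
        model = npx.fit_logistic(m, y, ["P"])
        assert model.separation_flag
        assert npx.empirical_auc(model.prob, y) == 1.0

    def test_pure_noise_cv_auc_near_half(self, rng):
        hits = []
        for rep in range(100):
            r = np.random.default_rng(rep)
            x = r.normal(size=(120, 2))
            m = _two_group_matrix({"A": x[:, 0], "B": x[:, 1]}, 60, 60)
            y = np.array([0] * 60 + [1] * 60)
            hits.append(npx.cross_validated_auc(m, y, ["A", "B"], k=5, seed=rep))
        assert abs(np.mean(hits) - 0.5) < 0.05


class TestReferenceModel:
    def test_missing_age_sample_excluded(self, clean_cohort):
        sub, y = npx.make_contrast(clean_cohort, npx.BENIGN_VS_CANCER)
        model = npx.reference_model(sub, y)
        assert model.n_excluded == 1
        assert len(model.sample_ids) == sub.n_samples - 1
        assert model.predictors == ["WFDC2", "MUC-16", "age"]

    def test_missing_marker_column_named(self, clean_cohort):
        sub, y = npx.make_contrast(clean_cohort, npx.BENIGN_VS_CANCER)
        crippled = NpxMatrix(sub.meta, sub.values.drop(columns=["MUC-16"]))
        with pytest.raises(KeyError, match="MUC-16"):
            npx.reference_model(crippled, y)

    def test_permuted_labels_give_chance_cv_auc(self, clean_cohort):
        # cross-validated, since apparent in-sample AUC is optimistically
        # biased above 0.5 even under the null
        sub, y = npx.make_contrast(clean_cohort, npx.BENIGN_VS_CANCER)
        aucs = []
        for rep in range(20):
            yp = np.random.default_rng(rep).permutation(y)
            aucs.append(
                npx.cross_validated_auc(sub, yp, list(models.CORE_PREDICTORS), k=5, seed=rep)
            )
        assert abs(np.mean(aucs) - 0.5) < 0.06

    def test_dominates_univariate_markers_under_independence(self, clean_cohort):
        sub, y = npx.make_contrast(clean_cohort, npx.BENIGN_VS_CANCER)
        model = npx.reference_model(sub, y)
        model_auc = npx.empirical_auc(model.prob, model.labels)
        keep = np.isin(sub.sample_ids, model.sample_ids)
        best_single = max(
            npx.empirical_auc(sub.values[p].to_numpy()[keep], y[keep])
            for p in ("WFDC2", "MUC-16")
        )
        assert model_auc >= best_single - 0.02


class TestAddOneScan:
    def test_duplicate_of_core_marker_adds_nothing(self, clean_cohort, rng):
        sub, y = npx.make_contrast(clean_cohort, npx.BENIGN_VS_CANCER)
        values = sub.values.copy()
        values["HE4_COPY"] = values["WFDC2"]
        m = NpxMatrix(sub.meta, values)
        _, rows = models.add_one_scan(m, y, ["HE4_COPY"], n_boot=50, seed=0)
        assert len(rows) == 1
        assert abs(rows[0].delong.auc_a - rows[0].delong.auc_b) < 0.01
        assert rows[0].delong.p > 0.9

    def test_core_candidates_skipped(self, clean_cohort):
        sub, y = npx.make_contrast(clean_cohort, npx.BENIGN_VS_CANCER)
        _, rows = models.add_one_scan(sub, y, ["WFDC2", "age"], n_boot=10, seed=0)
        assert rows == []

    def test_row_count_and_ranking(self, clean_cohort):
        sub, y = npx.make_contrast(clean_cohort, npx.BENIGN_VS_CANCER)
        cands = ["ITGAV", "DNER", "IL6", "NOISE_001"]
        ref_row, rows = models.add_one_scan(sub, y, cands, n_boot=20, seed=0)
        assert len(rows) == 4
        aucs = [r.evaluation.auc.auc for r in rows]
        assert aucs == sorted(aucs, reverse=True)
        assert [r.rank for r in rows] == [1, 2, 3, 4]

    def test_added_signal_raises_delong_rejection_rate(self):
        """The add-one DeLong test is size-calibrated on a null candidate
        and clearly powered on a strong independent candidate."""
        n_rep = 200
        hits = {True: 0, False: 0}
        for informative in (True, False):
            for rep in range(n_rep):
                m = npx.simulate_planted_cohort(
                    30,
                    116,
                    n_planted=1 if informative else 0,
                    effect=1.0,
                    n_noise=0 if informative else 1,
                    seed=rep,
                )
                sub, y = npx.make_contrast(m, npx.BENIGN_VS_CANCER)
                cand = "SIG_01" if informative else "NOISE_01"
                _, rows = models.add_one_scan(sub, y, [cand], n_boot=0, seed=rep)
                hits[informative] += rows[0].delong.p < 0.05
        assert hits[False] <= 0.10 * n_rep  # size near the nominal level
        assert hits[True] >= 0.125 * n_rep  # power well above the null rate
        assert hits[True] > 2 * hits[False]


class TestEvaluation:
    def test_perfect_model_all_ones(self):
        x = np.array([0, 1, 2, 3, 10, 11, 12, 13.0])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        m = _two_group_matrix({"P": x}, 4, 4)
        model = npx.fit_logistic(m, y, ["P"])
        ev = npx.evaluate_model(model, n_boot=50, seed=0, include_youden=True)
        assert ev.auc.auc == 1.0
        assert ev.sens_at_spec.sensitivity == 1.0
        assert ev.spec_at_sens.specificity == 1.0
        assert ev.youden.sensitivity == ev.youden.specificity == 1.0

    def test_same_seed_reproduces_cis(self, clean_cohort):
        sub, y = npx.make_contrast(clean_cohort, npx.BENIGN_VS_CANCER)
        model = npx.reference_model(sub, y)
        a = npx.evaluate_model(model, n_boot=100, seed=9)
        b = npx.evaluate_model(model, n_boot=100, seed=9)
        assert (a.auc.ci_low, a.auc.ci_high) == (b.auc.ci_low, b.auc.ci_high)
        assert a.sens_at_spec.ci_low == b.sens_at_spec.ci_low

    def test_single_marker_model_tracks_binormal_oracle(self):
        """Apparent AUC of the HE4-only logistic model averages to the
        closed-form binormal AUC of the HE4 group parameters."""
        truth = npx.binormal_auc(7.37, 0.72, 8.33, 0.64)
        aucs = []
        for rep in range(500):
            rng = np.random.default_rng(10_000 + rep)
            s, y = npx.simulate_two_group(7.37, 0.72, 8.33, 0.64, 30, 116, rng)
            aucs.append(npx.empirical_auc(s, y))  # logistic on one marker is monotone in it
        assert abs(np.mean(aucs) - truth) < 0.04
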