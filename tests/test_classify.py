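"""Penalized multinomial logistic regression on marker z-scores."""

import numpy as np
import pandas as pd
import pytest

from iemscreen.classify import (
    MLRModel,
    confusion_matrix,
    fit_mlr,
    linear_predictors,
    odds_ratios,
    predict,
    predict_table,
)
from iemscreen.pipeline import fit_group_model


def _toy_model(coef, markers=("m1",), classes=("control", "case")):
    return MLRModel(
        classes=tuple(classes),
        markers=tuple(markers),
        coef=np.asarray(coef, dtype=float),
        l2_penalty=0.01,
        reference_class=classes[0],
    )


class TestLinearPredictors:
    def test_zero_coefficients(self):
        m = _toy_model([[0.0, 0.0], [0.0, 0.0]])
        eta = linear_predictors(m, {"m1": 2.0})
        assert (eta == 0).all()

    def test_unit_slope(self):
        m = _toy_model([[0.0, 0.0], [0.0, 1.0]])
        eta = linear_predictors(m, {"m1": 2.0})
        assert eta["case"] == pytest.approx(2.0)
        assert eta["control"] == 0.0

    def test_hand_arithmetic(self):
        m = _toy_model(
            [[0.0, 0.0, 0.0], [1.0, 2.0, -1.0]], markers=("m1", "m2")
        )
        eta = linear_predictors(m, {"m1": 3.0, "m2": 4.0})
        assert eta["case"] == pytest.approx(1 + 6 - 4)

    def test_missing_marker_rejected(self):
        m = _toy_model([[0.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="missing"):
            linear_predictors(m, {"other": 1.0})


class TestPredict:
    def test_equal_predictors_tie_break_by_declared_order(self):
        m = _toy_model([[0.0, 0.0], [0.0, 0.0]])
        label, probs = predict(m, {"m1": 1.0})
        assert label == "control"
        assert np.allclose(probs, 0.5)

    def test_softmax_limit(self):
        m = _toy_model([[0.0, 0.0], [10.0, 0.0]])
        label, probs = predict(m, {"m1": 0.0})
        assert label == "case"
        assert probs["case"] > 0.9999

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(0)
        m = _toy_model(
            [[0.0, 0.0, 0.0], [0.3, -1.2, 2.0], [-0.5, 0.7, 0.1]],
            markers=("m1", "m2"),
            classes=("control", "A", "B"),
        )
        for _ in range(10):
            _, probs = predict(m, {"m1": rng.normal(), "m2": rng.normal()})
            assert probs.sum() == pytest.approx(1.0)
            assert (probs >= 0).all()


class TestOddsRatios:
    def test_zero_beta_is_unit_odds(self):
        m = _toy_model([[0.0, 0.0], [0.0, 0.0]])
        table = odds_ratios(m)
        assert (table["odds_ratio"] == 1.0).all()
        assert not table["beyond_range"].any()

    def test_log_two(self):
        m = _toy_model([[0.0, 0.0], [0.0, np.log(2.0)]])
        table = odds_ratios(m)
        assert table["odds_ratio"].iloc[0] == pytest.approx(2.0)

    def test_beyond_reportable_range_flagged(self):
        m = _toy_model([[0.0, 0.0], [0.0, 8.0]])  # OR ~ 2981 > 999
        assert odds_ratios(m)["beyond_range"].all()

    def test_reference_class_omitted(self):
        m = _toy_model([[0.0, 0.0], [0.0, 1.0]])
        assert set(odds_ratios(m)["class"]) == {"case"}


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        labels = ["control"] * 3 + ["PA"] * 2
        cm = confusion_matrix(labels, labels, ["control", "PA"])
        assert cm.loc["control", "control"] == 3
        assert cm.loc["PA", "PA"] == 2
        assert cm.to_numpy().sum() == 5

    def test_all_predicted_control_single_column(self):
        cm = confusion_matrix(
            ["control"] * 4, ["control", "PA", "PA", "MMA"],
            ["control", "PA", "MMA"],
        )
        assert cm["control"].sum() == 4
        assert cm[["PA", "MMA"]].to_numpy().sum() == 0

    def test_single_swap(self):
        cm = confusion_matrix(
            ["PA", "control"], ["control", "control"], ["control", "PA"]
        )
        assert cm.loc["control", "PA"] == 1

    def test_row_sums_equal_cohort_sizes(self):
        actual = ["control"] * 5 + ["PA"] * 3
        pred = ["control", "PA"] * 4
        cm = confusion_matrix(pred, actual, ["control", "PA"])
        assert cm.sum(axis=1).tolist() == [5, 3]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            confusion_matrix(["X"], ["control"], ["control", "PA"])


def _toy_data(n=40, shift=4.0, seed=0):
    rng = np.random.default_rng(seed)
    z = np.concatenate([rng.normal(0, 1, n), rng.normal(shift, 1, n)])
    labels = ["control"] * n + ["case"] * n
    frame = pd.DataFrame({"m1": z})
    return frame, labels


class TestFitMLR:
    def test_separated_data_finite_coefficients_and_perfect_accuracy(self):
        z, labels = _toy_data(shift=8.0, seed=1)
        m = fit_mlr(z, labels, ["m1"], l2_penalty=0.01)
        assert np.all(np.isfinite(m.coef))
        pred = predict_table(m, z)
        assert (pred == np.array(labels)).all()

    def test_reference_class_row_is_zero(self):
        z, labels = _toy_data(seed=2)
        m = fit_mlr(z, labels, ["m1"])
        ref = m.classes.index(m.reference_class)
        assert np.all(m.coef[ref] == 0)
        assert m.reference_class == "control"

    def test_null_data_gives_near_zero_coefficients(self):
        rng = np.random.default_rng(3)
        z = pd.DataFrame({"m1": rng.normal(0, 1, 400)})
        labels = list(rng.choice(["control", "case"], 400))
        m = fit_mlr(z, labels, ["m1"])
        assert abs(m.coef[1, 1]) < 0.3
        pred = predict_table(m, z)
        acc = (pred == np.array(labels)).mean()
        prior = max(labels.count("control"), labels.count("case")) / 400
        assert acc == pytest.approx(prior, abs=0.1)

    def test_duplicate_marker_rejected(self):
        z, labels = _toy_data()
        with pytest.raises(ValueError, match="duplicate"):
            fit_mlr(z, labels, ["m1", "m1"])

    def test_separation_without_penalty_reports_divergence(self):
        z, labels = _toy_data(shift=10.0, seed=4)
        with pytest.raises(RuntimeError, match="converge"):
            fit_mlr(z, labels, ["m1"], l2_penalty=0.0)

    def test_deterministic(self):
        z, labels = _toy_data(seed=5)
        a = fit_mlr(z, labels, ["m1"])
        b = fit_mlr(z, labels, ["m1"])
        assert np.array_equal(a.coef, b.coef)

    def test_grid_search_oracle(self):
        """The L-BFGS optimum of the penalized likelihood matches a
        brute-force grid search on a 2-class / 1-marker toy."""
        z, labels = _toy_data(n=40, shift=2.0, seed=6)
        lam = 0.1
        m = fit_mlr(z, labels, ["m1"], l2_penalty=lam)
        x = z["m1"].to_numpy()
        y = (np.array(labels) == "case").astype(float)

        def objective(b0, b1):
            eta = b0 + b1 * x
            return -np.sum(y * eta - np.logaddexp(0.0, eta)) + 0.5 * lam * b1**2

        b0s = np.linspace(-8, 8, 321)
        b1s = np.linspace(-8, 8, 321)
        grid = np.array([[objective(a, b) for b in b1s] for a in b0s])
        i, j = np.unravel_index(np.argmin(grid), grid.shape)
        fitted = objective(m.coef[1, 0], m.coef[1, 1])
        assert fitted <= grid[i, j] + 1e-6
        assert m.coef[1, 0] == pytest.approx(b0s[i], abs=0.06)
        assert m.coef[1, 1] == pytest.approx(b1s[j], abs=0.06)

    def test_regularization_path_monotone(self):
        z, labels = _toy_data(n=30, shift=3.0, seed=7)
        norms = [
            np.linalg.norm(fit_mlr(z, labels, ["m1"], l2_penalty=lam).coef)
            for lam in (0.01, 0.1, 1.0, 10.0)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_agrees_with_sklearn_predictions(self):
        sklearn = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(8)
        z = pd.DataFrame(
            {
                "m1": np.concatenate(
                    [rng.normal(0, 1, 60), rng.normal(3, 1, 30),
                     rng.normal(-2, 1, 30)]
                ),
                "m2": np.concatenate(
                    [rng.normal(0, 1, 60), rng.normal(-2, 1, 30),
                     rng.normal(3, 1, 30)]
                ),
            }
        )
        labels = ["control"] * 60 + ["A"] * 30 + ["B"] * 30
        m = fit_mlr(z, labels, ["m1", "m2"], l2_penalty=0.01)
        skm = sklearn.LogisticRegression(C=100.0, max_iter=5000)
        skm.fit(z.to_numpy(), labels)
        ours = predict_table(m, z).to_numpy()
        theirs = skm.predict(z.to_numpy())
        assert (ours == theirs).mean() > 0.97


class TestGroupAClassification:
    def test_pa_mma_confusion_matrix_is_diagonal(
        self, sim_params, signatures, marker_groups, panel, zscore_model
    ):
        """18 PA + 25 MMA + 341 controls, five propionate-pathway
        markers: every case lands on the diagonal."""
        group = marker_groups["group_A"]
        _, cm, _, _ = fit_group_model(
            group, sim_params, signatures, zscore_model, panel,
            n_controls=341, n_cases={"PA": 18, "MMA": 25}, seed=123,
        )
        assert cm.loc["PA", "PA"] == 18
        assert cm.loc["MMA", "MMA"] == 25
        off_diag = cm.to_numpy().sum() - np.trace(cm.to_numpy())
        assert off_diag == 0

    def test_group_models_have_expected_classes(
        self, sim_params, signatures, marker_groups, panel, zscore_model
    ):
        group = marker_groups["group_C"]
        mlr, cm, _, _ = fit_group_model(
            group, sim_params, signatures, zscore_model, panel,
            n_controls=100, n_cases={d: 8 for d in group.diseases}, seed=9,
        )
        assert mlr.classes == ("control", "VLCAD", "CPT2", "TFP")
        assert list(cm.index) == ["control", "VLCAD", "CPT2", "TFP"]
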