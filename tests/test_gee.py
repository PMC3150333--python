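"""GEE: factor coding, sandwich identities, screening, forward selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from igeprofile.gee import (
    classification_from_gee,
    encode_class_factor,
    forward_select,
    gee_fit,
    univariate_screen,
    wald_or_ci,
)
from igeprofile.matrix import ReactivityMatrix, Unit


def _logit_response(rng, eta):
    return (rng.random(len(eta)) < 1.0 / (1.0 + np.exp(-eta))).astype(int)


class TestEncodeClassFactor:
    def test_class_five_merges_into_four(self):
        design = encode_class_factor([5, 4, 0])
        assert design.loc[0, "score4"] == 1.0
        assert design.loc[1, "score4"] == 1.0
        assert design.loc[0].drop("score4").sum() == 0.0

    def test_class_zero_is_reference(self):
        design = encode_class_factor([0, 0])
        assert design.to_numpy().sum() == 0.0

    def test_indicators_mutually_exclusive(self):
        design = encode_class_factor([0, 1, 2, 3, 4, 5])
        assert (design.sum(axis=1) <= 1).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            encode_class_factor([0, 6])
        with pytest.raises(ValueError):
            encode_class_factor([-1])


class TestWaldOrCi:
    def test_zero_coefficient(self):
        res = wald_or_ci(0.0, 0.5)
        assert res["or_"] == 1.0
        assert res["wald_chi2"] == 0.0
        assert res["p"] == 1.0

    def test_identities_hold(self):
        res = wald_or_ci(1.2, 0.3)
        assert res["or_"] == pytest.approx(np.exp(1.2))
        assert res["ci_low"] == pytest.approx(np.exp(1.2 - 1.96 * 0.3))
        assert res["ci_high"] == pytest.approx(np.exp(1.2 + 1.96 * 0.3))
        assert res["wald_chi2"] == pytest.approx((1.2 / 0.3) ** 2)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            wald_or_ci(1.0, 0.0)


class TestGeeFit:
    def test_singleton_clusters_match_ordinary_logistic(self):
        rng = np.random.default_rng(0)
        n = 400
        x1 = rng.normal(size=n)
        x2 = rng.integers(0, 2, size=n).astype(float)
        y = _logit_response(rng, -0.4 + 0.9 * x1 - 0.6 * x2)
        design = pd.DataFrame({"x1": x1, "x2": x2})
        fit = gee_fit(y, design, [f"c{i}" for i in range(n)])
        # independent oracle: unpenalized logistic regression
        lr = LogisticRegression(penalty=None, tol=1e-10, max_iter=5000)
        lr.fit(design.to_numpy(), y)
        coefs = fit.table.set_index("term")["coefficient"]
        assert coefs["const"] == pytest.approx(lr.intercept_[0], abs=1e-5)
        assert coefs["x1"] == pytest.approx(lr.coef_[0][0], abs=1e-5)
        assert coefs["x2"] == pytest.approx(lr.coef_[0][1], abs=1e-5)
        assert fit.alpha_hat == pytest.approx(0.0, abs=1e-8)

    def test_duplicating_clusters_shrinks_robust_se(self):
        rng = np.random.default_rng(1)
        n_fam, fam_size = 80, 3
        fam = np.repeat(np.arange(n_fam), fam_size)
        u = rng.normal(0, 0.8, size=n_fam)[fam]
        x = rng.normal(size=n_fam * fam_size)
        y = _logit_response(rng, 0.5 * x + u)
        design = pd.DataFrame({"x": x})
        base = gee_fit(y, design, [f"f{g}" for g in fam])
        doubled = gee_fit(
            np.tile(y, 2), pd.concat([design, design], ignore_index=True),
            [f"f{g}" for g in fam] + [f"g{g}" for g in fam])
        b = base.table.set_index("term")
        d = doubled.table.set_index("term")
        assert d.loc["x", "coefficient"] == pytest.approx(b.loc["x", "coefficient"],
                                                          abs=1e-8)
        assert d.loc["x", "robust_se"] == pytest.approx(
            b.loc["x", "robust_se"] / np.sqrt(2), rel=0.02)

    def test_sandwich_invariant_to_cluster_relabeling_and_order(self):
        rng = np.random.default_rng(2)
        n = 150
        fam = rng.integers(0, 40, size=n)
        x = rng.normal(size=n)
        y = _logit_response(rng, 0.7 * x)
        design = pd.DataFrame({"x": x})
        base = gee_fit(y, design, [f"f{g}" for g in fam])
        order = rng.permutation(n)
        perm = gee_fit(y[order], design.iloc[order].reset_index(drop=True),
                       [f"relabeled{fam[i]}" for i in order])
        assert perm.table.set_index("term")["robust_se"]["x"] == pytest.approx(
            base.table.set_index("term")["robust_se"]["x"], rel=1e-5)

    def test_fewer_than_two_clusters_rejected(self):
        with pytest.raises(ValueError):
            gee_fit([0, 1], pd.DataFrame({"x": [0.0, 1.0]}), ["a", "a"])


def _score_matrix(values):
    values = np.asarray(values, dtype=float)
    return ReactivityMatrix(
        [f"s{i}" for i in range(values.shape[0])],
        [f"a{j}" for j in range(values.shape[1])],
        values, Unit.CLASS_SCORE,
    )


def _family_cohort(rng, n_fam=150, fam_size=3, n_allergens=8, effect=1.5,
                   signal_cols=(0,)):
    """Small clustered cohort with class-score columns, some predictive."""
    n = n_fam * fam_size
    fam = np.repeat(np.arange(n_fam), fam_size)
    u = rng.normal(0, 0.5, size=n_fam)[fam]
    y = (rng.random(n) < 0.5).astype(int)
    # baseline spans all levels in both groups (avoids complete separation)
    scores = np.clip(
        rng.integers(0, 3, size=(n, n_allergens)) + rng.poisson(0.4, size=(n, n_allergens)),
        0, 5).astype(float)
    for j in signal_cols:
        shifted = np.clip(scores[:, j] + rng.poisson(effect, size=n) * y, 0, 5)
        scores[:, j] = shifted
    return _score_matrix(scores), y, [f"f{g}" for g in fam], u


class TestUnivariateScreen:
    def test_planted_column_retained_nulls_mostly_not(self):
        rng = np.random.default_rng(3)
        matrix, y, fams, _ = _family_cohort(rng, signal_cols=(0, 1))
        screen = univariate_screen(matrix, y, fams)
        assert bool(screen.loc[0, "retained"])
        assert bool(screen.loc[1, "retained"])
        assert screen.loc[2:, "retained"].mean() < 0.5

    def test_null_retention_near_alpha(self):
        # per-cohort counts are the replicates (tests within a cohort share
        # one response vector); their mean should match binomial(6, 0.05)
        counts = []
        for seed in range(12):
            rng = np.random.default_rng(100 + seed)
            matrix, y, fams, _ = _family_cohort(rng, n_fam=80, n_allergens=6,
                                                signal_cols=())
            screen = univariate_screen(matrix, y, fams)
            counts.append(int(screen["retained"].sum()))
        from scipy import stats

        band = stats.binom.interval(0.95, 6, 0.05)
        assert band[0] <= np.mean(counts) <= band[1]


class TestForwardSelect:
    def _covariates(self, rng, n):
        age = rng.uniform(10, 70, size=n)
        male = rng.integers(0, 2, size=n).astype(float)
        return pd.DataFrame({"age": age, "male": male, "age_x_male": age * male})

    def test_strong_planted_allergen_enters_first(self):
        first_hits = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            matrix, y, fams, _ = _family_cohort(rng, n_fam=100, effect=2.0,
                                                signal_cols=(2,))
            fit, selected = forward_select(
                matrix, list(matrix.allergen_ids), y, fams,
                self._covariates(rng, len(y)))
            if selected and selected[0] == "a2":
                first_hits += 1
        assert first_hits >= 9

    def test_empty_candidates_give_covariates_only(self):
        rng = np.random.default_rng(4)
        matrix, y, fams, _ = _family_cohort(rng, n_fam=60, signal_cols=())
        with pytest.warns(UserWarning, match="covariates-only"):
            fit, selected = forward_select(matrix, [], y, fams,
                                           self._covariates(rng, len(y)))
        assert selected == []
        assert {"age", "male", "age_x_male"} <= set(fit.table["term"])

    def test_collinear_duplicate_excluded(self):
        rng = np.random.default_rng(5)
        matrix, y, fams, _ = _family_cohort(rng, n_fam=100, effect=2.0,
                                            signal_cols=(0,))
        values = matrix.values.copy()
        values[:, 1] = values[:, 0]  # perfect copy of the signal column
        dup = _score_matrix(values)
        fit, selected = forward_select(dup, ["a0", "a1"], y, fams,
                                       self._covariates(rng, len(y)))
        assert "a0" in selected
        assert "a1" not in selected


class TestClassificationFromGee:
    def test_planted_cohort_recovers_status(self, planted_features):
        # full planted cohort (12 signature allergens, 1.5 SD shift):
        # the signature factors jointly separate asthmatic subjects
        subjects, matrix, labels = planted_features
        fams = [s.family_id for s in subjects]
        signature = [f"A{j:03d}" for j in range(0, 24, 2)]
        parts = []
        for a in signature:
            j = matrix.allergen_ids.index(a)
            parts.append(encode_class_factor(matrix.values[:, j], prefix=f"{a}_s"))
        design = pd.concat(parts, axis=1)
        fit = gee_fit(labels, design, fams)
        out = classification_from_gee(fit, design, labels)
        assert out["sensitivity"] > 0.8
        assert out["specificity"] > 0.8

    def test_all_probabilities_above_threshold(self):
        rng = np.random.default_rng(7)
        n = 120
        fams = [f"f{i // 3}" for i in range(n)]
        y = rng.integers(0, 2, size=n)
        y[:4] = [0, 1, 0, 1]
        design = pd.DataFrame({"x": rng.normal(size=n)})
        fit = gee_fit(y, design, fams)
        out = classification_from_gee(fit, design, y, threshold=-0.01)
        assert out["sensitivity"] == 1.0
        assert out["specificity"] == 0.0
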