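"""ROC analysis and the logistic composite index: AUC conventions, Youden
cut-offs, DeLong intervals, IRLS fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcnet import (
    CompositeIndexClassifier,
    PerfectSeparationError,
    composite_roc,
    fit_logistic,
    roc_curve,
    youden_cutoff,
)

from conftest import rng_for


def auc_pair_oracle(values, labels):
    """O(n^2) concordant-pair count with the half-tie convention."""
    pos = values[labels == 1]
    neg = values[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def youden_oracle(values, labels):
    """Exhaustive scan of criterion 'positive if value > c' over all
    observed values and -inf; ties broken by higher sensitivity, then lower
    cut-off."""
    best = None
    for c in sorted(set(values.tolist())) + [-np.inf]:
        sens = np.mean(values[labels == 1] > c)
        spec = np.mean(values[labels == 0] <= c)
        j = sens + spec - 1
        key = (round(j, 12), round(sens, 12), -c if np.isfinite(c) else np.inf)
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    return best[1], best[2] * 100, best[3] * 100


class TestRocCurve:
    def test_perfect_separation(self):
        res = roc_curve([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1])
        assert res.auc == 1.0
        assert res.youden == pytest.approx(1.0)
        assert res.sensitivity == 100.0 and res.specificity == 100.0
        assert res.cutoff == pytest.approx(2.0)

    def test_all_values_tied(self):
        res = roc_curve([5.0] * 8, [0, 1] * 4)
        assert res.auc == 0.5
        assert res.youden == pytest.approx(0.0)

    def test_matches_pair_counting_oracle(self):
        rng = rng_for(20)
        for _ in range(100):
            n = int(rng.integers(8, 30))
            values = rng.integers(0, 6, n).astype(float)  # forces ties
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, max(2, n // 3), replace=False)] = 1
            res = roc_curve(values, labels)
            expect = auc_pair_oracle(values, labels)
            assert res.auc == pytest.approx(max(expect, 1 - expect), abs=1e-12)
            # trapezoid area of the reported curve equals the AUC
            assert np.trapezoid(res.tpr, res.fpr) == pytest.approx(res.auc, abs=1e-12)

    def test_curve_is_monotone_and_anchored(self):
        rng = rng_for(21)
        values = rng.normal(size=40)
        labels = (rng.random(40) < 0.4).astype(int)
        res = roc_curve(values, labels)
        assert res.fpr[0] == 0.0 and res.tpr[0] == 0.0
        assert res.fpr[-1] == 1.0 and res.tpr[-1] == 1.0
        assert np.all(np.diff(res.fpr) >= 0) and np.all(np.diff(res.tpr) >= 0)
        assert res.ci_low <= res.auc <= res.ci_high

    def test_matches_sklearn_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = rng_for(22)
        values = rng.normal(size=60) + 0.8 * (rng.random(60) < 0.5)
        labels = (rng.random(60) < 0.5).astype(int)
        if labels.sum() in (0, 60):
            labels[0] = 1 - labels[0]
        res = roc_curve(values, labels)
        ref = roc_auc_score(labels, values)
        assert res.auc == pytest.approx(max(ref, 1 - ref), abs=1e-12)

    def test_orientation_flip_recorded(self):
        values = np.array([4.0, 3.0, 2.0, 1.0])
        res = roc_curve(values, [0, 0, 1, 1])  # low values mark positives
        assert res.orientation == -1
        assert res.auc == 1.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0, 3.0], [0, 1, 2])

    def test_youden_matches_exhaustive_scan(self):
        rng = rng_for(23)
        for _ in range(50):
            n = int(rng.integers(10, 26))
            values = np.round(rng.normal(size=n), 1)
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, n // 2, replace=False)] = 1
            res = roc_curve(values, labels)
            oriented = values * res.orientation
            c_ref, sens_ref, spec_ref = youden_oracle(oriented, labels)
            cut, sens, spec = youden_cutoff(res)
            assert sens == pytest.approx(sens_ref, abs=1e-9)
            assert spec == pytest.approx(spec_ref, abs=1e-9)
            got = oriented > (cut * res.orientation if np.isfinite(cut) else c_ref)
            want = oriented > c_ref
            assert np.array_equal(got, want)

    def test_delong_ci_matches_r_proc(self, tmp_path):
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = rng_for(24)
        values = np.round(rng.normal(size=40) + 1.1 * (np.arange(40) < 18), 6)
        labels = (np.arange(40) < 18).astype(int)
        res = roc_curve(values, labels)
        script = tmp_path / "delong.R"
        script.write_text(
            "suppressMessages(library(pROC))\n"
            f"v <- c({', '.join(map(str, values))})\n"
            f"y <- c({', '.join(map(str, labels))})\n"
            "r <- roc(y, v, quiet=TRUE, direction='<')\n"
            "ci <- ci.auc(r, method='delong')\n"
            "cat(sprintf('%.10f %.10f %.10f', ci[1], ci[2], ci[3]))\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        ).stdout.split()
        lo, auc_ref, hi = map(float, out)
        assert res.auc == pytest.approx(auc_ref, abs=1e-10)
        assert res.ci_low == pytest.approx(lo, abs=1e-6)
        assert res.ci_high == pytest.approx(hi, abs=1e-6)


@settings(deadline=None, max_examples=40)
@given(
    st.lists(st.integers(0, 8), min_size=6, max_size=24),
    st.data(),
)
def test_auc_symmetry_under_negation(raw_values, data):
    values = np.asarray(raw_values, dtype=float)
    n = len(values)
    n_pos = data.draw(st.integers(1, n - 1))
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    fwd = auc_pair_oracle(values, labels)
    bwd = auc_pair_oracle(-values, labels)
    assert fwd + bwd == pytest.approx(1.0)
    # the reported (oriented) AUC agrees with the larger direction
    res = roc_curve(values, labels)
    assert res.auc == pytest.approx(max(fwd, bwd), abs=1e-12)


class TestLogistic:
    def test_zero_linear_predictor_gives_half(self):
        from dcnet.roc import LRModel

        model = LRModel(
            a0=0.0, coefficients=np.zeros(2), n_iter=0, converged=True,
            X=np.zeros((1, 2)), y=np.zeros(1),
        )
        np.testing.assert_allclose(
            model.predict_proba(np.random.default_rng(0).normal(size=(9, 2))), 0.5
        )

    def test_recovers_known_coefficients(self):
        rng = rng_for(25)
        n = 10_000
        x = rng.normal(size=(n, 1))
        z = -1.0 + 2.0 * x[:, 0]
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-z))).astype(int)
        model = fit_logistic(x, y)
        assert model.a0 == pytest.approx(-1.0, abs=0.1)
        assert model.coefficients[0] == pytest.approx(2.0, abs=0.1)

    def test_score_equations_hold_at_mle(self):
        rng = rng_for(26)
        x = rng.normal(size=(200, 3))
        y = (rng.random(200) < 0.4).astype(int)
        model = fit_logistic(x, y)
        p = model.predict_proba(x)
        assert abs(np.sum(y - p)) < 1e-6
        np.testing.assert_allclose(x.T @ (y - p), 0.0, atol=1e-6)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = rng_for(27)
        x = rng.normal(size=(150, 2))
        y = (rng.random(150) < 1 / (1 + np.exp(-(0.3 + 0.8 * x[:, 0])))).astype(int)
        model = fit_logistic(x, y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert model.a0 == pytest.approx(ref.params[0], abs=1e-6)
        np.testing.assert_allclose(model.coefficients, ref.params[1:], atol=1e-6)

    def test_perfect_separation_raises(self):
        x = np.r_[np.zeros(10), np.ones(10)][:, None]
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        with pytest.raises(PerfectSeparationError):
            fit_logistic(x, y)


class TestComposite:
    def _informative(self, seed, n=300, k=2):
        rng = rng_for(seed)
        y = (rng.random(n) < 0.5).astype(int)
        x = rng.normal(size=(n, k)) + 0.8 * y[:, None]
        return x, y

    def test_single_column_composite_equals_single_index(self):
        x, y = self._informative(28, k=1)
        model = fit_logistic(x, y)
        comp = composite_roc(model, x, y)
        single = roc_curve(x[:, 0], y)
        assert comp.auc == pytest.approx(single.auc, abs=1e-12)

    def test_composite_dominates_singles_at_large_n(self):
        x, y = self._informative(29, n=2000, k=2)
        model = fit_logistic(x, y)
        comp = composite_roc(model, x, y)
        singles = [roc_curve(x[:, j], y).auc for j in range(2)]
        assert comp.auc >= max(singles) - 0.01

    def test_label_permutation_is_null(self):
        rng = rng_for(30)
        x, y = self._informative(30, n=400)
        y_perm = rng.permutation(y)
        model = fit_logistic(x, y_perm)
        comp = composite_roc(model, x, y_perm)
        assert comp.auc < 0.60

    def test_affine_rescaling_invariance(self):
        x, y = self._informative(31)
        x2 = x.copy()
        x2[:, 0] = 40.0 * x2[:, 0] - 7.0
        a = composite_roc(fit_logistic(x, y), x, y)
        b = composite_roc(fit_logistic(x2, y), x2, y)
        assert a.auc == pytest.approx(b.auc, abs=1e-9)

    def test_sklearn_estimator_contract(self):
        from sklearn.base import clone
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler

        x, y = self._informative(32)
        clf = CompositeIndexClassifier()
        assert clone(clf).get_params() == clf.get_params()
        pipe = Pipeline([("scale", StandardScaler()), ("lr", clf)])
        pipe.fit(x, y)
        proba = pipe.predict_proba(x)
        assert proba.shape == (len(y), 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert pipe.score(x, y) > 0.6
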