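"""ROC, DeLong, agreement and proportion statistics."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from myoflow.diagnostics import (DiagnosticsError, bland_altman, cohen_kappa,
                                 delong_compare, diagnostic_metrics, roc_auc,
                                 two_sample_t)


def mann_whitney_auc(scores, labels):
    """Brute-force pair counting (ties one half) — the AUC oracle."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestROC:
    def test_worked_example(self):
        r = roc_auc([0.9, 0.4, 0.8, 0.3], [1, 1, 0, 0], low_is_positive=False)
        assert r.auc == pytest.approx(0.75)  # 3 of 4 pairs concordant

    def test_perfect_separation(self):
        r = roc_auc([1.0, 1.2, 3.0, 3.5], [1, 1, 0, 0], low_is_positive=True)
        assert r.auc == pytest.approx(1.0)

    def test_trapezoid_equals_pair_counting_with_ties(self, rng):
        """Exact equality with the Mann–Whitney statistic for n <= 50."""
        for _ in range(25):
            n = int(rng.integers(4, 50))
            scores = rng.integers(0, 8, n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            r = roc_auc(scores, labels, low_is_positive=False)
            assert r.auc == pytest.approx(mann_whitney_auc(scores, labels),
                                          abs=1e-12)

    def test_matches_sklearn(self, rng):
        scores = rng.normal(size=300)
        labels = rng.integers(0, 2, 300)
        r = roc_auc(scores, labels, low_is_positive=False)
        assert r.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_null_auc_near_half(self, rng):
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, 4000)
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(DiagnosticsError):
            roc_auc([1.0, 2.0], [1, 1])


class TestYouden:
    def test_separable_toy(self):
        r = roc_auc([1, 2, 3, 4], [1, 1, 0, 0], low_is_positive=True)
        assert r.youden_threshold == pytest.approx(2.5)
        assert r.youden_sensitivity == 1.0 and r.youden_specificity == 1.0

    def test_equals_exhaustive_search(self, rng):
        """Reported J is maximal over every enumerated cut."""
        for _ in range(20):
            scores = rng.normal(size=60)
            labels = rng.integers(0, 2, 60)
            if labels.min() == labels.max():
                continue
            r = roc_auc(scores, labels, low_is_positive=True)
            j = r.sensitivity + r.specificity - 1.0
            assert r.youden_j == pytest.approx(j.max(), abs=1e-12)

    def test_all_scores_identical(self):
        r = roc_auc([2.0, 2.0, 2.0, 2.0], [1, 0, 1, 0], low_is_positive=True)
        assert r.youden_j == pytest.approx(0.0, abs=1e-12)


class TestDeLong:
    def test_identical_scores(self):
        d = delong_compare([1, 2, 3, 4], [1, 2, 3, 4], [1, 1, 0, 0])
        assert d.diff == 0.0 and d.p_value == 1.0

    def test_sign_matches_empirical_aucs(self, rng):
        labels = rng.integers(0, 2, 80)
        labels[:5] = 1
        labels[-5:] = 0
        a = rng.normal(size=80) - labels  # informative, low = positive
        b = rng.normal(size=80)
        d = delong_compare(a, b, labels, low_is_positive=True)
        ra = roc_auc(a, labels).auc
        rb = roc_auc(b, labels).auc
        assert d.auc_a == pytest.approx(ra, abs=1e-12)
        assert d.auc_b == pytest.approx(rb, abs=1e-12)
        assert np.sign(d.diff) == np.sign(ra - rb)

    def test_variance_matches_bootstrap(self):
        """DeLong single-AUC variance vs 2000 seeded resamples, 40 cases."""
        rng = np.random.default_rng(7)
        labels = np.array([1] * 16 + [0] * 24)
        scores = np.where(labels == 1, rng.normal(1.4, 0.5, 40),
                          rng.normal(2.1, 0.7, 40))
        d = delong_compare(scores, scores, labels, low_is_positive=True)
        boot = []
        for _ in range(2000):
            idx = rng.integers(0, 40, 40)
            if labels[idx].min() == labels[idx].max():
                continue
            boot.append(roc_auc(scores[idx], labels[idx]).auc)
        assert d.var_a == pytest.approx(np.var(boot, ddof=1), rel=0.15)

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(DiagnosticsError):
            delong_compare([1, 2], [1, 2, 3], [1, 0, 1])


class TestBlandAltman:
    def test_identical_arrays(self):
        r = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.bias == 0.0 and r.loa_low == 0.0 and r.loa_high == 0.0

    def test_constant_offset(self):
        r = bland_altman([2.0, 3.0], [1.0, 2.0])
        assert r.bias == pytest.approx(1.0) and r.sd == pytest.approx(0.0)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=30)
        assert bland_altman(a, b).bias == pytest.approx(-bland_altman(b, a).bias)

    def test_recovers_true_mean_difference(self, rng):
        a = rng.normal(0.4, 1.0, 500)
        b = rng.normal(0.0, 1.0, 500)
        r = bland_altman(a, b)
        se = np.sqrt(2.0 / 500)
        assert abs(r.bias - 0.4) < 3 * se

    def test_too_short(self):
        with pytest.raises(DiagnosticsError):
            bland_altman([1.0], [2.0])


class TestKappa:
    def test_perfect_agreement(self):
        k = cohen_kappa([0, 1, 2, 0, 1], [0, 1, 2, 0, 1])
        assert k.kappa == pytest.approx(1.0)

    def test_worked_2x2_table(self):
        """a=10, b=2, c=2, d=10: p_o = 20/24, p_e = 1/2, kappa = 2/3."""
        a = [0] * 12 + [1] * 12
        b = [0] * 10 + [1] * 2 + [0] * 2 + [1] * 10
        k = cohen_kappa(a, b)
        assert k.p_observed == pytest.approx(20 / 24)
        assert k.p_expected == pytest.approx(0.5)
        assert k.kappa == pytest.approx(2 / 3)
        lo, hi = k.ci
        assert lo < 2 / 3 < hi

    def test_independent_raters_near_zero(self, rng):
        a = rng.integers(0, 2, 3000)
        b = rng.integers(0, 2, 3000)
        assert cohen_kappa(a, b).kappa == pytest.approx(0.0, abs=0.06)

    def test_relabel_invariance(self, rng):
        a = rng.integers(0, 3, 200)
        b = rng.integers(0, 3, 200)
        relabel = {0: 7, 1: 5, 2: 9}
        k1 = cohen_kappa(a, b)
        k2 = cohen_kappa([relabel[x] for x in a], [relabel[x] for x in b])
        assert k1.kappa == pytest.approx(k2.kappa, abs=1e-12)

    def test_undefined_when_both_constant(self):
        with pytest.raises(DiagnosticsError):
            cohen_kappa([1, 1, 1], [1, 1, 1])


class TestWelch:
    def test_same_sample(self):
        t, dof, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_textbook_formula_on_fixed_example(self):
        """Welch t and dof recomputed from first principles."""
        x = np.array([2.1, 2.5, 2.3, 2.7, 2.4])
        y = np.array([1.8, 1.6, 2.0, 1.7, 1.9])
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        se2 = vx / 5 + vy / 5
        t_ref = (x.mean() - y.mean()) / np.sqrt(se2)
        dof_ref = se2**2 / ((vx / 5)**2 / 4 + (vy / 5)**2 / 4)
        t, dof, _ = two_sample_t(x, y)
        assert t == pytest.approx(t_ref, rel=1e-12)
        assert dof == pytest.approx(dof_ref, rel=1e-12)

    def test_detects_unit_shift(self, rng):
        x = rng.normal(0, 1, 200)
        y = rng.normal(1, 1, 200)
        _, _, p = two_sample_t(x, y)
        assert p < 0.05

    def test_small_group_rejected(self):
        with pytest.raises(DiagnosticsError):
            two_sample_t([1.0], [1.0, 2.0])


class TestDiagnosticMetrics:
    def test_perfect_sensitivity(self):
        m = diagnostic_metrics(tp=10, fp=3, tn=7, fn=0)
        assert m.sensitivity == 1.0

    def test_all_half(self):
        m = diagnostic_metrics(5, 5, 5, 5)
        for v in (m.sensitivity, m.specificity, m.ppv, m.npv):
            assert v == pytest.approx(0.5)

    def test_zero_denominator_named(self):
        with pytest.raises(DiagnosticsError, match="specificity"):
            diagnostic_metrics(tp=5, fp=0, tn=0, fn=5)

    def test_wilson_cis_bracket_estimates(self, rng):
        """1000 random tables: CIs inside [0,1] and containing the point."""
        for _ in range(1000):
            tp, fp, tn, fn = rng.integers(1, 40, 4)
            m = diagnostic_metrics(int(tp), int(fp), int(tn), int(fn))
            for est, (lo, hi) in [
                (m.sensitivity, m.sensitivity_ci), (m.specificity, m.specificity_ci),
                (m.ppv, m.ppv_ci), (m.npv, m.npv_ci),
            ]:
                assert 0.0 <= lo <= est <= hi <= 1.0
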