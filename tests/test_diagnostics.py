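"""ROC/AUC, Youden, confusion metrics, DeLong, Bland-Altman, Pearson."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from coro0d.diagnostics import (
    LabeledScores,
    bland_altman,
    confusion_metrics,
    delong_test,
    evaluate_index,
    pearson,
    roc_auc,
    youden_cutoff,
)


def random_scores(rng, n=80, separation=1.0, ties=False):
    labels = rng.integers(0, 2, n)
    scores = rng.normal(labels * separation, 1.0)
    if ties:
        scores = np.round(scores, 1)
    if labels.sum() in (0, n):  # force both classes
        labels[0] = 1 - labels[0]
    return LabeledScores(scores, labels)


class TestAUC:
    def test_perfect_separation(self):
        d = LabeledScores([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert roc_auc(d)[1] == 1.0

    def test_all_tied_scores_give_half(self):
        d = LabeledScores(np.ones(10), [0, 1] * 5)
        assert roc_auc(d)[1] == 0.5

    def test_toy_set_matches_pairwise_concordance(self):
        d = LabeledScores([0.1, 0.4, 0.35, 0.8, 0.8, 0.2],
                          [0, 0, 1, 1, 0, 1])
        pos = d.scores[d.labels == 1]
        neg = d.scores[d.labels == 0]
        brute = np.mean([
            1.0 if p > q else 0.5 if p == q else 0.0
            for p in pos for q in neg
        ])
        assert roc_auc(d)[1] == pytest.approx(brute, rel=1e-12)

    @pytest.mark.parametrize("ties", [False, True])
    def test_matches_sklearn_oracle(self, rng, ties):
        for _ in range(5):
            d = random_scores(rng, ties=ties)
            assert roc_auc(d)[1] == pytest.approx(
                roc_auc_score(d.labels, d.scores), rel=1e-12
            )

    def test_invariant_under_monotone_transform(self, rng):
        d = random_scores(rng)
        d2 = LabeledScores(np.exp(d.scores), d.labels)
        assert roc_auc(d)[1] == pytest.approx(roc_auc(d2)[1], rel=1e-12)

    def test_orientation_flip(self, rng):
        d = random_scores(rng)
        flipped = LabeledScores(-d.scores, d.labels, higher_is_positive=False)
        assert roc_auc(d)[1] == pytest.approx(roc_auc(flipped)[1], rel=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(LabeledScores([1.0, 2.0], [1, 1]))


class TestYouden:
    def test_separated_toy_case(self):
        d = LabeledScores([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        cutoff, j = youden_cutoff(d)
        assert cutoff == 0.8
        assert j == pytest.approx(1.0)

    def test_anti_separated_with_flipped_orientation(self):
        d = LabeledScores([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1],
                          higher_is_positive=False)
        _, j = youden_cutoff(d)
        assert j == pytest.approx(1.0)

    def test_equals_exhaustive_threshold_scan(self, rng):
        for _ in range(5):
            d = random_scores(rng, n=150, ties=True)
            cutoff, j = youden_cutoff(d)
            best_j, best_cut = -np.inf, None
            for t in np.unique(d.scores):
                pred = d.scores >= t
                sens = pred[d.labels == 1].mean()
                spec = (~pred[d.labels == 0]).mean()
                if sens + spec - 1 > best_j + 1e-15:
                    best_j, best_cut = sens + spec - 1, t
            assert j == pytest.approx(best_j, rel=1e-12)
            assert cutoff == best_cut

    def test_random_labels_give_small_j(self, rng):
        labels = rng.integers(0, 2, 4000)
        d = LabeledScores(rng.normal(0, 1, 4000), labels)
        _, j = youden_cutoff(d)
        assert j < 0.1


class TestConfusionMetrics:
    def test_counted_rates(self):
        # TP=51, FN=2, TN=51, FP=2 -> sensitivity = accuracy = 96.23%
        scores = np.concatenate([
            np.ones(51), np.zeros(2),  # positives
            np.zeros(51), np.ones(2),  # negatives
        ])
        labels = np.concatenate([np.ones(53), np.zeros(53)]).astype(int)
        m = confusion_metrics(LabeledScores(scores, labels), 0.5)
        assert m["sensitivity"] == pytest.approx(96.2264, abs=1e-3)
        assert m["specificity"] == pytest.approx(96.2264, abs=1e-3)
        assert m["accuracy"] == pytest.approx(96.2264, abs=1e-3)
        assert m["ppv"] == pytest.approx(96.2264, abs=1e-3)

    def test_cutoff_below_all_scores(self, rng):
        d = random_scores(rng)
        m = confusion_metrics(d, d.scores.min() - 1)
        assert m["sensitivity"] == 100.0
        assert m["specificity"] == 0.0
        assert m["npv"] is None  # no negative predictions

    def test_matches_direct_counting(self, rng):
        d = random_scores(rng, n=60, ties=True)
        cutoff = float(np.median(d.scores))
        m = confusion_metrics(d, cutoff)
        pred = d.scores >= cutoff
        tp = int(np.sum(pred & (d.labels == 1)))
        fp = int(np.sum(pred & (d.labels == 0)))
        assert m["tp"] == tp and m["fp"] == fp
        assert m["accuracy"] == pytest.approx(
            100 * np.mean(pred == d.labels), rel=1e-12
        )

    def test_infinite_cutoff_rejected(self, rng):
        with pytest.raises(ValueError):
            confusion_metrics(random_scores(rng), np.inf)


class TestDeLong:
    def test_identical_scores_give_z_zero_p_one(self, rng):
        d = random_scores(rng)
        z, p = delong_test(d, d)
        assert z == 0.0
        assert p == 1.0

    def test_rank_invariance(self, rng):
        a = random_scores(rng)
        b = LabeledScores(rng.normal(a.labels * 0.5, 1.0), a.labels)
        z1, _ = delong_test(a, b)
        a2 = LabeledScores(np.exp(2 * a.scores), a.labels)
        b2 = LabeledScores(b.scores**3 + 7, b.labels)
        z2, _ = delong_test(a2, b2)
        assert z1 == pytest.approx(z2, rel=1e-12)

    def test_unpaired_inputs_rejected(self, rng):
        a = random_scores(rng)
        b = LabeledScores(a.scores, 1 - a.labels)
        with pytest.raises(ValueError):
            delong_test(a, b)

    def test_variance_close_to_stratified_bootstrap(self):
        rng = np.random.default_rng(99)
        n = 20
        labels = np.array([0, 1] * (n // 2))
        latent = rng.normal(labels * 1.2, 1.0)
        a = LabeledScores(latent + rng.normal(0, 0.6, n), labels)
        b = LabeledScores(latent + rng.normal(0, 0.6, n), labels)
        z, _ = delong_test(a, b)
        _, auc_a = roc_auc(a)
        _, auc_b = roc_auc(b)
        var_delong = ((auc_a - auc_b) / z) ** 2 if z != 0 else np.nan

        pos_idx = np.flatnonzero(labels == 1)
        neg_idx = np.flatnonzero(labels == 0)
        diffs = np.empty(10_000)
        for k in range(10_000):
            pi = rng.choice(pos_idx, pos_idx.size, replace=True)
            ni = rng.choice(neg_idx, neg_idx.size, replace=True)
            idx = np.concatenate([pi, ni])
            lab = labels[idx]
            da = LabeledScores(a.scores[idx], lab)
            db = LabeledScores(b.scores[idx], lab)
            diffs[k] = roc_auc(da)[1] - roc_auc(db)[1]
        var_boot = diffs.var(ddof=1)
        assert var_delong == pytest.approx(var_boot, rel=0.15)

    def test_null_calibration_under_label_permutation(self):
        rng = np.random.default_rng(7)
        n = 100
        labels = np.array([0] * (n // 2) + [1] * (n // 2))
        latent = rng.normal(0, 1, n)
        sa = latent + rng.normal(0, 0.8, n)
        sb = latent + rng.normal(0, 0.8, n)
        n_rep = 2000
        rejections = 0
        for _ in range(n_rep):
            perm = rng.permutation(labels)
            z, p = delong_test(LabeledScores(sa, perm), LabeledScores(sb, perm))
            if p is not None and p < 0.05:
                rejections += 1
        rate = rejections / n_rep
        assert 0.03 <= rate <= 0.07


class TestAgreement:
    def test_bland_altman_identity(self):
        x = np.linspace(0, 1, 10)
        bias, (lo, hi) = bland_altman(x, x)
        assert bias == 0.0 and lo == 0.0 and hi == 0.0

    def test_bland_altman_constant_shift(self):
        x = np.linspace(0.5, 1.0, 20)
        bias, (lo, hi) = bland_altman(x, x - 0.01)
        assert bias == pytest.approx(0.01)
        assert lo == pytest.approx(0.01) and hi == pytest.approx(0.01)

    def test_bland_altman_matches_direct_formula(self, rng):
        x = rng.normal(0.8, 0.1, 40)
        y = x + rng.normal(0.0, 0.05, 40)
        bias, (lo, hi) = bland_altman(x, y)
        d = x - y
        assert bias == pytest.approx(d.mean(), rel=1e-12)
        assert hi - bias == pytest.approx(1.96 * d.std(ddof=1), rel=1e-12)

    def test_bland_altman_needs_two_pairs(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [1.0])

    def test_pearson_affine_and_oracle(self, rng):
        x = rng.normal(0, 1, 30)
        r, _ = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r2, _ = pearson(x, -x)
        assert r2 == pytest.approx(-1.0)
        y = x + rng.normal(0, 0.5, 30)
        r3, p3 = pearson(x, y)
        rr, pp = stats.pearsonr(x, y)
        assert r3 == pytest.approx(rr, abs=1e-12)
        assert p3 == pytest.approx(pp, abs=1e-12)

    def test_pearson_constant_rejected(self):
        with pytest.raises(ValueError):
            pearson(np.ones(5), np.arange(5.0))


def test_evaluate_index_report_shape(rng):
    d = random_scores(rng, n=60, separation=2.0)
    comp = LabeledScores(rng.normal(d.labels * 1.0, 1.0), d.labels)
    ref = d.scores + rng.normal(0, 0.1, d.scores.size)
    report = evaluate_index(d, "chsr", comparators={"ffr_cfd": comp},
                            agreement_reference=ref)
    out = report.to_dict()
    assert 0.5 < out["auc"] <= 1.0
    assert "ffr_cfd" in out["delong"]
    assert out["bland_altman"]["lower_limit"] <= out["bland_altman"]["bias"]
    assert out["pearson"]["r"] > 0.9
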