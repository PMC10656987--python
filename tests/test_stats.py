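"""Statistical battery vs. independent brute-force oracles."""

from itertools import combinations

import numpy as np
import pytest

from icppulse.stats import (
    delong_auc_variance,
    delong_paired_test,
    mann_whitney,
    roc_analysis,
    run_association_study,
    shapiro_wilk_gate,
    spearman,
)
from icppulse.synth import CohortSpec, generate_cohort


# ---- independent oracles ------------------------------------------------

def brute_force_u(a, b) -> float:
    """Discordant-pair count with half credit for ties (U for group a)."""
    return float(sum(1.0 * (x > y) + 0.5 * (x == y) for x in a for y in b))


def brute_force_exact_p(a, b) -> float:
    """Two-sided exact p by exhaustive enumeration of group labelings."""
    pooled = list(a) + list(b)
    n = len(a)
    u_obs = brute_force_u(a, b)
    us = []
    for idx in combinations(range(len(pooled)), n):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(brute_force_u(ga, gb))
    us = np.array(us)
    cdf = np.mean(us <= u_obs + 1e-9)
    sf = np.mean(us >= u_obs - 1e-9)
    return float(min(1.0, 2.0 * min(cdf, sf)))


def brute_force_auc(scores, labels) -> float:
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    return brute_force_u(pos, neg) / (len(pos) * len(neg))


def spearman_closed_form(x, y) -> float:
    rx = np.argsort(np.argsort(x))
    ry = np.argsort(np.argsort(y))
    d2 = np.sum((rx - ry) ** 2)
    n = len(x)
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1))


# ---- Mann-Whitney -------------------------------------------------------

class TestMannWhitney:
    def test_worked_examples(self):
        r = mann_whitney([1, 2], [3, 4])
        assert r.u_statistic == 0.0
        assert r.p_value == pytest.approx(1 / 3)
        r = mann_whitney([5], [7])
        assert r.u_statistic == 0.0
        assert r.p_value == pytest.approx(1.0)
        r = mann_whitney([1, 2, 3], [1, 2, 3])
        assert r.p_value == pytest.approx(1.0, abs=1e-6)

    def test_u_matches_pair_counting_with_ties(self, rng):
        for _ in range(150):
            na, nb = rng.integers(1, 9, size=2)
            a = rng.integers(0, 6, na).astype(float)  # integer scores force ties
            b = rng.integers(0, 6, nb).astype(float)
            r = mann_whitney(a, b)
            assert r.u_statistic == pytest.approx(brute_force_u(a, b))

    def test_exact_p_matches_enumeration(self, rng):
        for _ in range(30):
            na, nb = rng.integers(2, 7, size=2)
            a, b = rng.normal(size=na), rng.normal(size=nb)
            r = mann_whitney(a, b)
            assert r.p_value == pytest.approx(brute_force_exact_p(a, b), abs=1e-12)

    def test_medians_and_errors(self):
        r = mann_whitney([1, 2, 3, 4], [10, 20])
        assert r.median_iqr_a == (2.5, 1.75, 3.25)
        assert (r.n_a, r.n_b) == (4, 2)
        with pytest.raises(ValueError):
            mann_whitney([], [1])

    def test_type_I_error_calibrated(self):
        rng = np.random.default_rng(7)
        n_sim = 3000
        rej = sum(
            mann_whitney(rng.normal(size=20), rng.normal(size=20)).p_value < 0.05
            for _ in range(n_sim)
        )
        assert abs(rej / n_sim - 0.05) <= 0.015


# ---- Spearman -----------------------------------------------------------

class TestSpearman:
    def test_worked_examples(self):
        assert spearman([1, 2, 3], [10, 20, 30]).rho == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [2, 1, 4, 3]).rho == pytest.approx(0.6)
        assert spearman([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)

    def test_matches_closed_form_tie_free(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            x = rng.permutation(n).astype(float)
            y = rng.permutation(n).astype(float)
            assert spearman(x, y).rho == pytest.approx(
                spearman_closed_form(x, y), abs=1e-12
            )

    def test_errors(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])


# ---- ROC / AUC ----------------------------------------------------------

class TestRoc:
    def test_worked_examples(self):
        r = roc_analysis([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert r.auc == pytest.approx(0.75)
        r = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0 and r.sensitivity == 1.0 and r.specificity == 1.0
        assert 3 <= r.threshold < 10
        assert roc_analysis([1.0] * 6, [0, 1, 0, 1, 0, 1]).auc == pytest.approx(0.5)

    def test_auc_matches_pairwise_oracle(self, rng):
        for _ in range(150):
            n = int(rng.integers(4, 30))
            scores = rng.integers(0, 8, n).astype(float)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert roc_analysis(scores, labels).auc == pytest.approx(
                brute_force_auc(scores, labels)
            )

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.4).astype(int)
        base = roc_analysis(scores, labels).auc
        assert roc_analysis(np.exp(scores), labels).auc == pytest.approx(base)
        assert roc_analysis(3 * scores - 7, labels).auc == pytest.approx(base)

    def test_delong_ci_contains_auc_and_shrinks(self):
        res_small = generate_cohort(CohortSpec(n_patients=60, seed=5))
        res_big = generate_cohort(CohortSpec(n_patients=600, seed=5))
        widths = []
        for res in (res_small, res_big):
            scores = [s.mean_psi for s in res.summaries]
            labels = [int(c.lesion_present) for c in res.cts]
            r = roc_analysis(scores, labels)
            assert r.ci95[0] <= r.auc <= r.ci95[1]
            widths.append(r.ci95[1] - r.ci95[0])
        assert widths[1] < widths[0]

    def test_bootstrap_ci_seeded_and_sane(self):
        scores = list(range(20))
        labels = [0] * 10 + [1] * 10
        r1 = roc_analysis(scores, labels, ci_method="bootstrap", seed=3)
        r2 = roc_analysis(scores, labels, ci_method="bootstrap", seed=3)
        assert r1.ci95 == r2.ci95

    def test_paired_delong_null_on_identical_scores(self):
        scores = np.arange(30.0)
        labels = (np.arange(30) % 2).astype(int)
        d, z, p = delong_paired_test(scores, scores, labels)
        assert d == 0.0 and p == 1.0

    def test_delong_variance_positive(self, rng):
        scores = rng.normal(size=50)
        labels = (rng.random(50) < 0.5).astype(int)
        auc, var = delong_auc_variance(scores, labels)
        assert 0 <= auc <= 1 and var > 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1, 2, 3], [1, 1, 1])


# ---- Shapiro gate -------------------------------------------------------

class TestShapiroGate:
    def test_heavy_tail_rejected(self):
        rejections = 0
        for seed in range(40):
            x = np.random.default_rng(seed).standard_cauchy(500)
            _, _, normal = shapiro_wilk_gate(x)
            rejections += not normal
        assert rejections >= 38  # >= 95%

    def test_normal_type_I_near_alpha(self):
        rej = 0
        n_seeds = 400
        for seed in range(n_seeds):
            x = np.random.default_rng(seed).normal(size=500)
            _, _, normal = shapiro_wilk_gate(x)
            rej += not normal
        assert abs(rej / n_seeds - 0.05) < 0.04

    def test_domain_bounds(self):
        with pytest.raises(ValueError):
            shapiro_wilk_gate([1.0, 2.0])
        with pytest.raises(ValueError):
            shapiro_wilk_gate(np.zeros(5001))


# ---- full battery -------------------------------------------------------

class TestAssociationStudy:
    def test_report_shape_at_study_group_sizes(self):
        # group sizes mirroring a 130-patient cohort (103/27 and 90/40)
        res = generate_cohort(CohortSpec(n_patients=130, seed=12))
        report = run_association_study(res.summaries, res.cts)
        assert report.n_patients == 130
        assert report.comparison_table().shape[0] == 3
        assert len(report.rocs) == 6
        assert report.correlation_table().shape[0] == 12
        assert len(report.auc_comparisons) == 4

    def test_null_cohort_no_inflation(self):
        pvals = []
        for seed in range(6):
            res = generate_cohort(CohortSpec(n_patients=130, severity_effect=0.0, seed=seed))
            report = run_association_study(res.summaries, res.cts)
            pvals += [r.p_value for r in report.group_comparisons.values()]
        # under the null, roughly uniform p-values
        assert np.mean(np.array(pvals) < 0.05) < 0.25
        assert np.mean(pvals) > 0.3

    def test_join_failure_raises(self):
        res = generate_cohort(CohortSpec(n_patients=20, seed=1))
        res.cts[0].patient_id = "mismatch"
        with pytest.raises(ValueError, match="join"):
            run_association_study(res.summaries, res.cts)
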