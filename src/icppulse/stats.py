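"""Nonparametric cohort statistics: normality gate, Mann-Whitney U,
Spearman correlation, and ROC analysis with threshold estimation.

The battery mirrors a standard neuromonitoring-cohort analysis: the
Shapiro-Wilk test justifies the nonparametric route, group contrasts use
the Mann-Whitney U test reported as median [Q1-Q3] per group, monotone
associations use Spearman's rho, and each metric's ability to identify
patients with a pathological CT finding is quantified by the area under
the ROC curve with a DeLong 95% CI and a Youden-optimal cutoff. The
significance level is 0.05 throughout, with no multiple-testing
correction by default (a Holm option is exposed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import CTAssessment, PatientSummary

__all__ = [
    "GroupComparisonResult",
    "CorrelationResult",
    "ROCResult",
    "shapiro_wilk_gate",
    "mann_whitney",
    "spearman",
    "roc_analysis",
    "delong_auc_variance",
    "delong_paired_test",
    "run_association_study",
    "AssociationReport",
]

ALPHA = 0.05


@dataclass
class GroupComparisonResult:
    u_statistic: float
    p_value: float
    median_iqr_a: tuple[float, float, float]  # median, Q1, Q3
    median_iqr_b: tuple[float, float, float]
    n_a: int
    n_b: int


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int


@dataclass
class ROCResult:
    auc: float
    ci95: tuple[float, float]
    threshold: float
    accuracy: float
    sensitivity: float
    specificity: float


def shapiro_wilk_gate(sample) -> tuple[float, float, bool]:
    """Shapiro-Wilk test; ``normal = (p >= 0.05)``. Valid for 3 <= n <= 5000."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    stat, p = sps.shapiro(x)
    return float(stat), float(p), bool(p >= ALPHA)


def _median_iqr(x: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    return float(med), float(q1), float(q3)


def mann_whitney(group_a, group_b) -> GroupComparisonResult:
    """Two-sided Mann-Whitney U test with per-group median [Q1-Q3].

    Uses the exact null distribution when ``nA*nB <= 400`` and the data
    are tie-free, otherwise the tie-corrected normal approximation.
    The U statistic reported is for ``group_a``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size * b.size <= 400 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparisonResult(
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        median_iqr_a=_median_iqr(a),
        median_iqr_b=_median_iqr(b),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation (mid-ranks for ties, t-approximation p).

    On tie-free data rho equals the closed form
    ``1 - 6*sum(d^2)/(n*(n^2-1))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("correlation undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p_value=float(p), n=int(x.size))


def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) method with half credit for ties."""
    n1 = int(labels.sum())
    n0 = labels.size - n1
    ranks = sps.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


def _delong_components(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # placement values via pairwise comparison with tie credit
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return v10, v01, float(psi.mean())


def delong_auc_variance(scores, labels) -> tuple[float, float]:
    """DeLong point AUC and its sampling variance."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    v10, v01, auc = _delong_components(scores, labels)
    # a single-member group contributes no estimable variance component
    var = sum(
        v.var(ddof=1) / v.size for v in (v10, v01) if v.size > 1
    )
    return auc, float(var)


def delong_paired_test(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """Paired DeLong comparison of two AUCs on the same subjects.

    Returns ``(auc_a - auc_b, z, two-sided p)``.
    """
    labels = np.asarray(labels, dtype=int)
    va10, va01, auc_a = _delong_components(np.asarray(scores_a, float), labels)
    vb10, vb01, auc_b = _delong_components(np.asarray(scores_b, float), labels)
    n1, n0 = va10.size, va01.size
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1 + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n0
    d = auc_a - auc_b
    if var <= 0:
        return d, 0.0 if d == 0 else np.inf * np.sign(d), 1.0 if d == 0 else 0.0
    z = d / np.sqrt(var)
    return float(d), float(z), float(2 * sps.norm.sf(abs(z)))


def _youden_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, float, float]:
    """Cutoff maximizing J = sensitivity + specificity - 1 under the
    strict ``score > threshold => positive`` convention. Ties in J break
    toward the lower threshold (higher sensitivity)."""
    best = (-np.inf, np.nan, np.nan, np.nan)  # J, thr, sens, spec
    n1 = labels.sum()
    n0 = labels.size - n1
    for thr in np.unique(scores):
        pred = scores > thr
        sens = np.sum(pred & (labels == 1)) / n1
        spec = np.sum(~pred & (labels == 0)) / n0
        j = sens + spec - 1
        if j > best[0] + 1e-12:
            best = (j, float(thr), float(sens), float(spec))
    _, thr, sens, spec = best
    pred = scores > thr
    acc = float(np.mean(pred == (labels == 1)))
    return thr, acc, sens, spec


def roc_analysis(scores, labels, ci_method: str = "delong", n_boot: int = 2000, seed: int = 0) -> ROCResult:
    """AUC with 95% CI and the Youden-optimal classification threshold.

    AUC uses the rank method with half credit for ties; the CI is DeLong
    by default, with a seeded stratified bootstrap as the alternative.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size != labels.size:
        raise ValueError("scores and labels must have equal length")
    if np.unique(labels).size < 2:
        raise ValueError("both label values must be present")
    auc = _auc_rank(scores, labels)
    if ci_method == "delong":
        _, var = delong_auc_variance(scores, labels)
        half = 1.959963984540054 * np.sqrt(max(var, 0.0))
        ci = (max(0.0, auc - half), min(1.0, auc + half))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos = np.where(labels == 1)[0]
        neg = np.where(labels == 0)[0]
        aucs = np.empty(n_boot)
        for i in range(n_boot):
            idx = np.concatenate(
                [rng.choice(pos, pos.size), rng.choice(neg, neg.size)]
            )
            aucs[i] = _auc_rank(scores[idx], labels[idx])
        ci = tuple(np.percentile(aucs, [2.5, 97.5]))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    thr, acc, sens, spec = _youden_threshold(scores, labels)
    return ROCResult(auc, (float(ci[0]), float(ci[1])), thr, acc, sens, spec)


METRICS = ("mean_icp", "amp_icp", "mean_psi")
BINARY_FEATURES = ("mls_present", "lesion_present")
CONTINUOUS_COVARIATES = ("midline_shift_mm", "lesion_volume_cm3", "marshall", "rotterdam")


@dataclass
class AssociationReport:
    """Full association battery for one cohort.

    Keys are ``(metric, feature)`` pairs; ``auc_comparisons`` holds the
    paired DeLong contrasts of mean-PSI AUC against the other metrics
    (an extension beyond the core battery, labelled as such in exports).
    """

    n_patients: int
    group_comparisons: dict = field(default_factory=dict)
    correlations: dict = field(default_factory=dict)
    rocs: dict = field(default_factory=dict)
    auc_comparisons: dict = field(default_factory=dict)

    def comparison_table(self) -> pd.DataFrame:
        """Group-contrast table: one metric per row, absent/present
        median [Q1-Q3] and Mann-Whitney p per binary CT feature."""
        rows = []
        for m in METRICS:
            row: dict = {"metric": m}
            for f in BINARY_FEATURES:
                r: GroupComparisonResult = self.group_comparisons[(m, f)]
                med_a, q1a, q3a = r.median_iqr_a
                med_b, q1b, q3b = r.median_iqr_b
                row[f"{f}_absent"] = f"{med_a:.2f} [{q1a:.2f}-{q3a:.2f}]"
                row[f"{f}_present"] = f"{med_b:.2f} [{q1b:.2f}-{q3b:.2f}]"
                row[f"{f}_p"] = r.p_value
            rows.append(row)
        return pd.DataFrame(rows)

    def correlation_table(self) -> pd.DataFrame:
        rows = [
            {"metric": m, "covariate": c, "rho": r.rho, "p": r.p_value, "n": r.n}
            for (m, c), r in self.correlations.items()
        ]
        return pd.DataFrame(rows)

    def roc_table(self) -> pd.DataFrame:
        rows = [
            {
                "metric": m,
                "feature": f,
                "auc": r.auc,
                "ci_low": r.ci95[0],
                "ci_high": r.ci95[1],
                "threshold": r.threshold,
                "accuracy": r.accuracy,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
            }
            for (m, f), r in self.rocs.items()
        ]
        return pd.DataFrame(rows)


def run_association_study(
    summaries: list[PatientSummary],
    cts: list[CTAssessment],
    ci_method: str = "delong",
    seed: int = 0,
) -> AssociationReport:
    """Join per-patient metrics with CT assessments and run the battery.

    For each metric in ``(mean_icp, amp_icp, mean_psi)``: Mann-Whitney U
    against both binary CT flags, Spearman against the four quantitative
    or ordinal covariates, and ROC/AUC against both flags.
    """
    by_id = {ct.patient_id: ct for ct in cts}
    pairs = [(s, by_id[s.patient_id]) for s in summaries if s.patient_id in by_id]
    if len(pairs) < len(summaries) or len(pairs) < len(cts):
        missing = {s.patient_id for s in summaries} ^ set(by_id)
        raise ValueError(f"patient_id join failure: unmatched ids {sorted(missing)[:5]}")
    df = pd.DataFrame(
        {
            "mean_icp": [s.mean_icp_mmHg for s, _ in pairs],
            "amp_icp": [s.amp_icp_mmHg for s, _ in pairs],
            "mean_psi": [s.mean_psi for s, _ in pairs],
            "midline_shift_mm": [c.midline_shift_mm for _, c in pairs],
            "lesion_volume_cm3": [c.lesion_volume_cm3 for _, c in pairs],
            "marshall": [c.marshall for _, c in pairs],
            "rotterdam": [c.rotterdam for _, c in pairs],
            "mls_present": [c.mls_present for _, c in pairs],
            "lesion_present": [c.lesion_present for _, c in pairs],
        }
    )
    report = AssociationReport(n_patients=len(df))
    for f in BINARY_FEATURES:
        flag = df[f].to_numpy(dtype=bool)
        if flag.sum() < 2 or (~flag).sum() < 2:
            raise ValueError(f"fewer than 2 patients per group for {f}")
        for m in METRICS:
            x = df[m].to_numpy()
            report.group_comparisons[(m, f)] = mann_whitney(x[~flag], x[flag])
            report.rocs[(m, f)] = roc_analysis(x, flag.astype(int), ci_method, seed=seed)
        for other in ("mean_icp", "amp_icp"):
            report.auc_comparisons[(("mean_psi", other), f)] = delong_paired_test(
                df["mean_psi"], df[other], flag.astype(int)
            )
    for m in METRICS:
        for c in CONTINUOUS_COVARIATES:
            report.correlations[(m, c)] = spearman(df[m], df[c])
    return report
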