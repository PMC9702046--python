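"""Group comparison, ROC cut-point and predictive-power statistics.

Implements the response-biomarker machinery: Mann–Whitney U and
Kruskal–Wallis comparisons with Bonferroni adjustment, empirical ROC
analysis with the AUC > 0.6 & p < 0.05 significance rule, Youden-index cut
points, and confusion-matrix metrics (sensitivity/specificity/PPV/NPV) with
exact Clopper–Pearson confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .phantom import POOR_RESPONSE, RESPONSE


@dataclass
class GroupComparison:
    feature: str
    regime: str
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    group_summaries: dict | None = None  # group -> {median, min, max, n}


@dataclass
class RocResult:
    thresholds: np.ndarray  # distinct scores, ascending; rule is score > c
    sensitivity: np.ndarray  # per threshold
    specificity: np.ndarray
    auc: float
    auc_se: float
    p_value: float  # vs AUC = 0.5
    significant: bool  # AUC > 0.6 and p < 0.05
    n_positive: int
    n_negative: int
    scores: np.ndarray
    labels: np.ndarray


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp

    def sensitivity(self) -> float:
        return 100.0 * self.tp / self.n_positive

    def specificity(self) -> float:
        return 100.0 * self.tn / self.n_negative

    def ppv(self) -> float:
        d = self.tp + self.fp
        return 100.0 * self.tp / d if d else float("nan")

    def npv(self) -> float:
        d = self.tn + self.fn
        return 100.0 * self.tn / d if d else float("nan")


@dataclass
class CutPointMetrics:
    """One cut-point row: threshold (rule: score > cut_point predicts
    response), Youden J, and the four predictive metrics in % with exact
    95% CIs."""

    cut_point: float
    youden_j: float
    confusion: ConfusionMatrix
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    ppv_ci: tuple[float, float]
    npv_ci: tuple[float, float]


def _check_nonempty(*groups) -> list[np.ndarray]:
    out = []
    for g in groups:
        a = np.asarray(g, dtype=float)
        if a.size == 0:
            raise ValueError("each group must contain at least one value")
        out.append(a)
    return out


def _summaries(named: dict[str, np.ndarray]) -> dict:
    return {
        k: {
            "median": float(np.median(v)),
            "min": float(v.min()),
            "max": float(v.max()),
            "n": int(v.size),
        }
        for k, v in named.items()
    }


def mann_whitney(
    values_a, values_b, feature: str = "", regime: str = ""
) -> GroupComparison:
    """Two-sided Mann–Whitney U test.

    Uses the exact null distribution when the combined sample is small
    (n <= 12) and tie-free, and the tie-corrected normal approximation
    (no continuity correction, so the k = 2 Kruskal–Wallis test agrees)
    otherwise.
    """
    a, b = _check_nonempty(values_a, values_b)
    combined = np.concatenate([a, b])
    no_ties = np.unique(combined).size == combined.size
    if np.ptp(combined) == 0:
        # degenerate: every observation identical
        u, p = len(a) * len(b) / 2.0, 1.0
    else:
        method = "exact" if (combined.size <= 12 and no_ties) else "asymptotic"
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method=method, use_continuity=False
        )
        u, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        feature=feature,
        regime=regime,
        statistic=u,
        p_value=min(p, 1.0),
        group_summaries=_summaries({"a": a, "b": b}),
    )


def kruskal_wallis(groups, feature: str = "", regime: str = "") -> GroupComparison:
    """Kruskal–Wallis H test (tie-corrected) with chi-square p on k-1 df."""
    gs = _check_nonempty(*groups)
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if np.ptp(np.concatenate(gs)) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*gs)
    return GroupComparison(
        feature=feature,
        regime=regime,
        statistic=float(h),
        p_value=float(p),
        group_summaries=_summaries({str(i): g for i, g in enumerate(gs)}),
    )


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("family size m must be >= number of p-values")
    return np.minimum(1.0, m * p)


def roc_analysis(scores, labels, positive: str = RESPONSE) -> RocResult:
    """Empirical ROC for predicting ``positive`` with the rule score > c.

    The AUC is the trapezoidal area of the empirical curve (equal to the
    Mann–Whitney U statistic scaled by n+ * n-); its p-value against the
    chance value 0.5 comes from the tie-corrected normal approximation of
    U.  The study's significance rule — AUC > 0.6 and p < 0.05 — is
    evaluated and returned as a flag.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    if not pos.any() or pos.all():
        raise ValueError("both classes must be present")
    s_pos, s_neg = scores[pos], scores[~pos]
    n_pos, n_neg = s_pos.size, s_neg.size

    thresholds = np.unique(scores)
    # rule score > c: predicted positive iff score strictly above threshold
    tp = (s_pos[None, :] > thresholds[:, None]).sum(axis=1)
    fp = (s_neg[None, :] > thresholds[:, None]).sum(axis=1)
    sens = tp / n_pos
    spec = 1 - fp / n_neg

    # full curve including the trivial corners, ascending false-positive rate
    fpr = np.concatenate([[0.0], (1 - spec)[::-1], [1.0]])
    tpr = np.concatenate([[0.0], sens[::-1], [1.0]])
    auc = float(np.trapezoid(tpr, fpr))

    # tie-corrected null variance of the U statistic; AUC = U / (n+ * n-)
    n = n_pos + n_neg
    _, counts = np.unique(scores, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n_pos * n_neg / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        p_value, se = 1.0, float("nan")
    else:
        se = math.sqrt(var_u) / (n_pos * n_neg)
        z = (auc - 0.5) / se
        p_value = float(2 * stats.norm.sf(abs(z)))

    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_se=se,
        p_value=p_value,
        significant=bool(auc > 0.6 and p_value < 0.05),
        n_positive=n_pos,
        n_negative=n_neg,
        scores=scores,
        labels=pos,
    )


def clopper_pearson(successes: int, trials: int, alpha: float = 0.05):
    """Exact binomial CI (beta quantiles), returned in percent."""
    if not (0 <= successes <= trials) or trials <= 0:
        raise ValueError("need 0 <= successes <= trials, trials > 0")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    k, n = successes, trials
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return 100.0 * low, 100.0 * high


def metrics_from_confusion(
    cm: ConfusionMatrix, cut_point: float = float("nan"), alpha: float = 0.05
) -> CutPointMetrics:
    """Sensitivity/specificity/PPV/NPV (%) with exact CIs for one threshold."""
    def ci(k, n):
        return clopper_pearson(k, n, alpha) if n else (float("nan"), float("nan"))

    return CutPointMetrics(
        cut_point=cut_point,
        youden_j=cm.sensitivity() / 100 + cm.specificity() / 100 - 1,
        confusion=cm,
        sensitivity=cm.sensitivity(),
        specificity=cm.specificity(),
        ppv=cm.ppv(),
        npv=cm.npv(),
        sensitivity_ci=ci(cm.tp, cm.n_positive),
        specificity_ci=ci(cm.tn, cm.n_negative),
        ppv_ci=ci(cm.tp, cm.tp + cm.fp),
        npv_ci=ci(cm.tn, cm.tn + cm.fn),
    )


def youden_cut_point(roc: RocResult, alpha: float = 0.05) -> CutPointMetrics:
    """Cut point maximising J = sensitivity + specificity - 1 over all
    distinct score thresholds; ties broken toward the smallest (most
    sensitive) threshold."""
    j = roc.sensitivity + roc.specificity - 1
    best = int(np.argmax(j))  # thresholds ascending -> first max is smallest c
    c = float(roc.thresholds[best])
    s_pos = roc.scores[roc.labels]
    s_neg = roc.scores[~roc.labels]
    cm = ConfusionMatrix(
        tp=int((s_pos > c).sum()),
        fp=int((s_neg > c).sum()),
        tn=int((s_neg <= c).sum()),
        fn=int((s_pos <= c).sum()),
    )
    return metrics_from_confusion(cm, cut_point=c, alpha=alpha)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def reconstruct_confusion(
    sensitivity_pct: float,
    specificity_pct: float,
    n_positive: int,
    n_negative: int,
) -> ConfusionMatrix:
    """Rebuild integer counts from printed sensitivity/specificity.

    tp = round(sens * n+ / 100) and tn = round(spec * n- / 100) with
    round-half-away-from-zero; this is the bridge that lets PPV/NPV be
    recomputed from a published table without patient-level data.
    """
    for v in (sensitivity_pct, specificity_pct):
        if not (0 <= v <= 100):
            raise ValueError("percentages must lie in [0, 100]")
    tp = _round_half_away(sensitivity_pct * n_positive / 100.0)
    tn = _round_half_away(specificity_pct * n_negative / 100.0)
    return ConfusionMatrix(tp=tp, fp=n_negative - tn, tn=tn, fn=n_positive - tp)
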