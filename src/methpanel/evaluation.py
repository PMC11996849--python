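"""Diagnostic-performance statistics.

Everything a blinded diagnostic trial reports from 2x2 tables and score
vectors: sensitivity/specificity/PPV/NPV/accuracy, the Youden index,
Cohen's kappa with an asymptotic CI, three binomial-proportion interval
constructions (Wilson score, Wald, Clopper–Pearson — clinical papers mix
them, so all three are first-class and every report labels its method),
empirical ROC curves with trapezoidal AUC, stratified tables, and the
paired pre/post Wilcoxon signed-rank comparison used for treatment
monitoring.

Metrics whose denominator is empty are reported as NaN and flagged,
never silently as 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .core import ConfusionCounts, ValidationError, as_percent

__all__ = [
    "MetricReport",
    "RocCurve",
    "confusion",
    "metrics",
    "kappa",
    "kappa_ci",
    "ci_wilson",
    "ci_wald",
    "ci_clopper_pearson",
    "proportion_ci",
    "roc",
    "stratified_report",
    "paired_pre_post",
    "two_group_rank_test",
]


# ---------------------------------------------------------------------------
# confusion table construction
# ---------------------------------------------------------------------------

def confusion(
    truth: Sequence[str],
    calls: Sequence[str],
    positive: str = "positive",
    negative: str = "negative",
    no_call: str = "no_call",
    no_call_policy: str = "exclude",
) -> ConfusionCounts:
    """Cross-tabulate truth labels against test calls.

    ``truth`` entries are ``positive``/``negative``; ``calls`` may also be
    ``no_call``, which by default is excluded from the counts (and warned
    about) rather than counted as a miss.
    """
    if len(truth) != len(calls):
        raise ValidationError(
            f"truth ({len(truth)}) and calls ({len(calls)}) differ in length"
        )
    tp = fp = fn = tn = 0
    n_no_call = 0
    for t, c in zip(truth, calls):
        if c == no_call:
            if no_call_policy != "exclude":
                raise ValidationError(f"unknown no_call policy {no_call_policy!r}")
            n_no_call += 1
            continue
        if t not in (positive, negative):
            raise ValidationError(f"unknown truth label {t!r}")
        if c not in (positive, negative):
            raise ValidationError(f"unknown call label {c!r}")
        if t == positive:
            tp += c == positive
            fn += c == negative
        else:
            fp += c == positive
            tn += c == negative
    if n_no_call:
        warnings.warn(
            f"{n_no_call} no_call sample(s) excluded from the confusion table",
            stacklevel=2,
        )
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


# ---------------------------------------------------------------------------
# point metrics and intervals
# ---------------------------------------------------------------------------

def _safe_ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


@dataclass
class MetricReport:
    """Point diagnostic metrics for one 2x2 table, with binomial CIs.

    ``cis`` maps metric name -> (lower, upper); undefined metrics are NaN
    and listed in ``undefined``. ``ci_method`` labels the construction.
    """

    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    youden_j: float
    kappa: float
    kappa_ci: tuple[float, float]
    cis: dict[str, tuple[float, float]]
    ci_method: str
    ci_level: float
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out: dict = {"counts": self.counts.as_dict()}
        for name in (
            "sensitivity", "specificity", "ppv", "npv", "accuracy", "youden_j"
        ):
            out[name] = getattr(self, name)
        out["kappa"] = self.kappa
        out["kappa_ci"] = list(self.kappa_ci)
        out["ci_method"] = self.ci_method
        out["ci_level"] = self.ci_level
        out["cis"] = {k: list(v) for k, v in self.cis.items()}
        out["undefined"] = list(self.undefined)
        return out


def ci_wilson(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion x/n."""
    _check_xn(x, n)
    z = stats.norm.ppf(1 - (1 - level) / 2)
    p = x / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    # the bound is exact at the boundaries; avoid float round-off there
    lo = 0.0 if x == 0 else max(center - half, 0.0)
    hi = 1.0 if x == n else min(center + half, 1.0)
    return lo, hi


def ci_wald(
    x: int, n: int, level: float = 0.95, clamp: bool = True
) -> tuple[float, float]:
    """Wald (normal-approximation) interval; clamped to [0, 1] by default."""
    _check_xn(x, n)
    z = stats.norm.ppf(1 - (1 - level) / 2)
    p = x / n
    half = z * math.sqrt(p * (1 - p) / n)
    lo, hi = p - half, p + half
    if clamp:
        lo, hi = max(lo, 0.0), min(hi, 1.0)
    return lo, hi


def ci_clopper_pearson(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper–Pearson exact interval (beta-quantile form)."""
    _check_xn(x, n)
    alpha = 1 - level
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


_CI_METHODS = {
    "wilson": ci_wilson,
    "wald": ci_wald,
    "clopper-pearson": ci_clopper_pearson,
}


def proportion_ci(
    x: int, n: int, level: float = 0.95, method: str = "wilson"
) -> tuple[float, float]:
    try:
        fn = _CI_METHODS[method]
    except KeyError:
        raise ValidationError(
            f"unknown CI method {method!r}; choose from {sorted(_CI_METHODS)}"
        ) from None
    return fn(x, n, level)


def _check_xn(x: int, n: int) -> None:
    if n <= 0 or not 0 <= x <= n:
        raise ValidationError(f"need 0 <= x <= n with n > 0, got x={x}, n={n}")


def metrics(
    c: ConfusionCounts,
    ci_method: str = "wilson",
    level: float = 0.95,
) -> MetricReport:
    """All point metrics for one confusion table, with labelled CIs."""
    sens = _safe_ratio(c.tp, c.tp + c.fn)
    spec = _safe_ratio(c.tn, c.tn + c.fp)
    ppv = _safe_ratio(c.tp, c.tp + c.fp)
    npv = _safe_ratio(c.tn, c.tn + c.fn)
    acc = _safe_ratio(c.tp + c.tn, c.total)
    youden = sens + spec - 1

    cis: dict[str, tuple[float, float]] = {}
    undefined: list[str] = []
    for name, (x, n) in {
        "sensitivity": (c.tp, c.tp + c.fn),
        "specificity": (c.tn, c.tn + c.fp),
        "ppv": (c.tp, c.tp + c.fp),
        "npv": (c.tn, c.tn + c.fn),
        "accuracy": (c.tp + c.tn, c.total),
    }.items():
        if n > 0:
            cis[name] = proportion_ci(x, n, level, ci_method)
        else:
            undefined.append(name)
            cis[name] = (float("nan"), float("nan"))
    if c.total == 0:
        undefined.extend(["youden_j", "kappa"])
        k, kci = float("nan"), (float("nan"), float("nan"))
    else:
        k = kappa(c)
        kci = kappa_ci(c, level)
    return MetricReport(
        counts=c,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        accuracy=acc,
        youden_j=youden,
        kappa=k,
        kappa_ci=kci,
        cis=cis,
        ci_method=ci_method,
        ci_level=level,
        undefined=undefined,
    )


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------

def kappa(c: ConfusionCounts) -> float:
    """Cohen's kappa for a 2x2 truth-vs-call table.

    ``(po - pe) / (1 - pe)`` with the chance agreement ``pe`` computed
    from the row/column marginals. Degenerate marginals (pe == 1) give NaN.
    """
    n = c.total
    if n == 0:
        raise ValidationError("kappa needs a nonempty table")
    po = (c.tp + c.tn) / n
    pe = (
        (c.tp + c.fn) * (c.tp + c.fp) + (c.fp + c.tn) * (c.fn + c.tn)
    ) / (n * n)
    if pe == 1.0:
        return float("nan")
    return (po - pe) / (1 - pe)


def kappa_ci(c: ConfusionCounts, level: float = 0.95) -> tuple[float, float]:
    """Asymptotic (Fleiss–Cohen–Everitt) confidence interval for kappa."""
    n = c.total
    k = kappa(c)
    if math.isnan(k):
        return float("nan"), float("nan")
    # cell proportions: rows = truth (pos, neg), cols = call (pos, neg)
    p = np.array([[c.tp, c.fn], [c.fp, c.tn]], dtype=float) / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    pe = float(row @ col)
    a = sum(
        p[i, i] * (1 - (row[i] + col[i]) * (1 - k)) ** 2 for i in range(2)
    )
    b = (1 - k) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2
        for i in range(2)
        for j in range(2)
        if i != j
    )
    cc = (k - pe * (1 - k)) ** 2
    var = (a + b - cc) / (n * (1 - pe) ** 2)
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(1 - (1 - level) / 2)
    return k - z * se, k + z * se


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class RocCurve:
    """Empirical ROC points (ties grouped) and the trapezoidal AUC.

    Higher score = more cancer-like. The AUC equals the Mann–Whitney
    concordance probability P(score_case > score_control) + ½P(tie).
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc(scores: Sequence[float], truth: Sequence[str], positive: str = "positive") -> RocCurve:
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([t == positive for t in truth], dtype=int)
    if len(scores) != len(y):
        raise ValidationError("scores and truth differ in length")
    if y.min() == y.max():
        raise ValidationError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


# ---------------------------------------------------------------------------
# stratified reporting
# ---------------------------------------------------------------------------

def stratified_report(
    truth: Sequence[str],
    calls: Sequence[str],
    strata: Sequence[str],
    ci_method: str = "wilson",
    level: float = 0.95,
) -> pd.DataFrame:
    """One metric row per stratum plus an ``overall`` row.

    Empty strata are kept and flagged (all-NaN metrics), not dropped;
    stratum counts sum exactly to the overall counts.
    """
    if not (len(truth) == len(calls) == len(strata)):
        raise ValidationError("truth, calls and strata must align")
    rows = []
    order = list(dict.fromkeys(strata))
    for stratum in order:
        idx = [i for i, s in enumerate(strata) if s == stratum]
        c = confusion([truth[i] for i in idx], [calls[i] for i in idx])
        rows.append((stratum, c))
    rows.append(("overall", confusion(truth, calls)))
    records = []
    for name, c in rows:
        rep = metrics(c, ci_method=ci_method, level=level)
        rec = {
            "stratum": name,
            **c.as_dict(),
            "n": c.total,
            "sensitivity": rep.sensitivity,
            "specificity": rep.specificity,
            "ppv": rep.ppv,
            "npv": rep.npv,
            "accuracy": rep.accuracy,
            "flagged_empty": c.total == 0,
        }
        for metric_name in ("sensitivity", "specificity"):
            lo, hi = rep.cis[metric_name]
            rec[f"{metric_name}_ci_low"] = lo
            rec[f"{metric_name}_ci_high"] = hi
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("stratum")


# ---------------------------------------------------------------------------
# paired and unpaired rank tests
# ---------------------------------------------------------------------------

def paired_pre_post(
    pre: Sequence[float], post: Sequence[float]
) -> tuple[float, float, int]:
    """Wilcoxon signed-rank test on paired pre/post scores.

    Two-sided; zero differences dropped (Wilcoxon's original treatment),
    ties mid-ranked. Returns (statistic, p_value, n_decreased). All-zero
    differences make the test undefined (NaN p) with a warning.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValidationError("pre and post must be paired (equal length)")
    n_decreased = int(np.sum(post < pre))
    diffs = post - pre
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; test undefined")
        return float("nan"), float("nan"), n_decreased
    res = stats.wilcoxon(
        post, pre, zero_method="wilcox", alternative="two-sided"
    )
    return float(res.statistic), float(res.pvalue), n_decreased


def two_group_rank_test(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann–Whitney U) for two independent groups —
    the unpaired counterpart to :func:`paired_pre_post`."""
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
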