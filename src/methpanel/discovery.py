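"""Marker discovery from region-level methylation matrices.

The screen looks for cancer-specific hypermethylation usable in plasma:
regions significantly more methylated in tumor than adjacent normal
tissue (rank-sum test, multiplicity-adjusted), with a tumor-minus-normal
mean difference above 0.1 and a white-blood-cell background mean below
0.1 (cfDNA is mostly leukocyte-derived, so a quiet WBC background is
what makes a tumor signal visible in plasma). Plasma matrices are then
one-hot transformed — per-region thresholds at the 95th percentile of
control plasma, values at or below threshold zeroed — and a regularised
logistic model ranks the surviving regions to pick the final panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GenomicRegion, MethylMatrix, ProbeRecord, ValidationError

__all__ = [
    "DmrResult",
    "OneHotMatrix",
    "MarkerModel",
    "harmonize_probes",
    "screen_dmrs",
    "dmr_table",
    "onehot_transform",
    "select_markers",
]


# ---------------------------------------------------------------------------
# probe harmonisation between two array platforms
# ---------------------------------------------------------------------------

def harmonize_probes(
    a: Sequence[ProbeRecord],
    b: Sequence[ProbeRecord],
    max_gap: int = 150,
) -> list[tuple[ProbeRecord, ProbeRecord]]:
    """Match probes across two platforms by genomic proximity.

    A pair is reported when the probe intervals overlap, or the
    end-to-start gap on the same chromosome is at most ``max_gap`` bp
    (inclusive). A probe may take part in several pairs; the pair set is
    symmetric in the two inputs. Pairs are returned sorted by position.
    """
    by_chrom: dict[str, list[ProbeRecord]] = {}
    for p in b:
        by_chrom.setdefault(p.region.chrom, []).append(p)
    for probes in by_chrom.values():
        probes.sort(key=lambda p: (p.region.start, p.region.end, p.probe_id))

    pairs: list[tuple[ProbeRecord, ProbeRecord]] = []
    for p in sorted(a, key=lambda p: (p.region.chrom, p.region.start, p.probe_id)):
        for q in by_chrom.get(p.region.chrom, []):
            if q.region.start > p.region.end + max_gap:
                break
            gap = p.region.gap_to(q.region)
            if gap is not None and gap <= max_gap:
                pairs.append((p, q))
    return pairs


# ---------------------------------------------------------------------------
# DMR screening
# ---------------------------------------------------------------------------

@dataclass
class DmrResult:
    """Per-region screen outcome against the three criteria."""

    region: GenomicRegion
    p_raw: float
    p_adj: float
    delta_t2n: float
    mean_wbc: float
    pass_p: bool
    pass_delta: bool
    pass_wbc: bool
    excluded: bool = False  # all-missing region, outside the adjustment

    @property
    def pass_overall(self) -> bool:
        return self.pass_p and self.pass_delta and self.pass_wbc


def screen_dmrs(
    m: MethylMatrix,
    groups: Optional[Mapping[str, str]] = None,
    alpha: float = 1e-2,
    min_delta: float = 0.1,
    max_wbc: float = 0.1,
    test: str = "ranksum",
    adjust: str = "fdr_bh",
) -> list[DmrResult]:
    """Screen every region for cancer-specific hypermethylation.

    Per region: a two-sample test of tumor vs adjacent-normal levels
    (Wilcoxon rank-sum by default, Welch t as option), adjusted across
    regions (Benjamini–Hochberg default, ``"bonferroni"`` available);
    ``delta_t2n`` and ``mean_wbc`` from available (non-missing) values.
    A region passes overall iff ``p_adj < alpha``, ``delta_t2n >
    min_delta`` and ``mean_wbc < max_wbc``. Results are sorted by
    ``p_adj`` ascending, ties broken by larger |delta_t2n|.
    """
    sample_groups = dict(m.groups if groups is None else groups)
    cols = {"tumor": [], "adjacent": [], "wbc": []}
    for s in m.sample_ids:
        g = sample_groups.get(s)
        if g in cols:
            cols[g].append(s)
    for needed in ("tumor", "adjacent"):
        if len(cols[needed]) < 2:
            raise ValidationError(
                f"screen requires >= 2 '{needed}' samples, found {len(cols[needed])}"
            )
    if not cols["wbc"]:
        raise ValidationError("screen requires 'wbc' background samples")

    tum = m.values[cols["tumor"]].to_numpy(dtype=float)
    adj = m.values[cols["adjacent"]].to_numpy(dtype=float)
    wbc = m.values[cols["wbc"]].to_numpy(dtype=float)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        delta = np.nanmean(tum, axis=1) - np.nanmean(adj, axis=1)
        mean_wbc = np.nanmean(wbc, axis=1)

    n_regions = tum.shape[0]
    p_raw = np.full(n_regions, np.nan)
    tum_ok = (~np.isnan(tum)).sum(axis=1) >= 2
    adj_ok = (~np.isnan(adj)).sum(axis=1) >= 2
    testable = tum_ok & adj_ok
    if test == "ranksum":
        # vectorised where nothing is missing; row-wise otherwise
        full = testable & ~np.isnan(tum).any(axis=1) & ~np.isnan(adj).any(axis=1)
        if full.any():
            res = stats.mannwhitneyu(
                tum[full], adj[full], axis=1, alternative="two-sided"
            )
            p_raw[full] = res.pvalue
        for i in np.nonzero(testable & ~full)[0]:
            t = tum[i][~np.isnan(tum[i])]
            a = adj[i][~np.isnan(adj[i])]
            p_raw[i] = stats.mannwhitneyu(t, a, alternative="two-sided").pvalue
    elif test == "ttest":
        for i in np.nonzero(testable)[0]:
            t = tum[i][~np.isnan(tum[i])]
            a = adj[i][~np.isnan(adj[i])]
            p_raw[i] = stats.ttest_ind(t, a, equal_var=False).pvalue
    else:
        raise ValidationError(f"unknown test {test!r}")

    p_adj = np.full(n_regions, np.nan)
    if testable.any():
        _, adj_vals, _, _ = multipletests(p_raw[testable], method=adjust)
        p_adj[testable] = adj_vals

    results = []
    for i, region in enumerate(m.regions):
        excluded = not testable[i]
        results.append(
            DmrResult(
                region=region,
                p_raw=float(p_raw[i]),
                p_adj=float(p_adj[i]),
                delta_t2n=float(delta[i]),
                mean_wbc=float(mean_wbc[i]),
                pass_p=bool(not excluded and p_adj[i] < alpha),
                pass_delta=bool(not np.isnan(delta[i]) and delta[i] > min_delta),
                pass_wbc=bool(not np.isnan(mean_wbc[i]) and mean_wbc[i] < max_wbc),
                excluded=excluded,
            )
        )
    results.sort(
        key=lambda r: (
            np.inf if np.isnan(r.p_adj) else r.p_adj,
            -abs(0.0 if np.isnan(r.delta_t2n) else r.delta_t2n),
        )
    )
    return results


def dmr_table(results: Sequence[DmrResult]) -> pd.DataFrame:
    """Flatten screen results to the report table schema."""
    return pd.DataFrame.from_records(
        [
            {
                "region": r.region.key,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "delta_t2n": r.delta_t2n,
                "mean_wbc": r.mean_wbc,
                "pass_p": r.pass_p,
                "pass_delta": r.pass_delta,
                "pass_wbc": r.pass_wbc,
                "pass_overall": r.pass_overall,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# one-hot plasma transform
# ---------------------------------------------------------------------------

@dataclass
class OneHotMatrix:
    """Thresholded plasma signals.

    Per region the threshold is the 95th percentile (linear interpolation
    between order statistics) of control plasma levels; a sample's signal
    is its methylation level when strictly above threshold, else 0.
    """

    thresholds: pd.Series  # region key -> threshold
    signals: pd.DataFrame  # region x sample, zeros below threshold
    detected: pd.DataFrame  # boolean companion


def onehot_transform(
    plasma: MethylMatrix,
    control_ids: Sequence[str],
    q: float = 0.95,
) -> OneHotMatrix:
    """Apply the control-percentile detection threshold per region.

    Detection is strict: a level exactly at the threshold is *not*
    detected, so with the 95th percentile at most ~5% of controls (plus
    percentile-interpolation slack of 1/n) light up per region.
    """
    control_ids = list(control_ids)
    if not control_ids:
        raise ValidationError("onehot_transform needs a nonempty control set")
    unknown = [s for s in control_ids if s not in plasma.values.columns]
    if unknown:
        raise ValidationError(f"control ids not in matrix: {unknown[:5]}")
    if len(control_ids) < 20:
        warnings.warn(
            f"only {len(control_ids)} controls; the {q:.0%} percentile "
            "threshold will be unstable",
            stacklevel=2,
        )
    controls = plasma.values[control_ids].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        thr = np.nanquantile(controls, q, axis=1, method="linear")
    thresholds = pd.Series(thr, index=plasma.values.index, name="threshold")
    levels = plasma.values.to_numpy(dtype=float)
    detected = levels > thr[:, None]
    detected &= ~np.isnan(levels)
    signals = np.where(detected, levels, 0.0)
    return OneHotMatrix(
        thresholds=thresholds,
        signals=pd.DataFrame(
            signals, index=plasma.values.index, columns=plasma.values.columns
        ),
        detected=pd.DataFrame(
            detected, index=plasma.values.index, columns=plasma.values.columns
        ),
    )


# ---------------------------------------------------------------------------
# logistic marker selection
# ---------------------------------------------------------------------------

@dataclass
class MarkerModel:
    """A fitted logistic diagnostic model over selected regions."""

    selected_regions: list[str]
    intercept: float
    coefficients: dict[str, float]
    n_training: int
    seed: Optional[int] = None
    C: float = 1.0
    ranking: pd.DataFrame = field(repr=False, default=None)

    def predict_proba(self, oh: OneHotMatrix) -> pd.Series:
        X = oh.signals.loc[self.selected_regions].to_numpy(dtype=float).T
        beta = np.array([self.coefficients[r] for r in self.selected_regions])
        z = self.intercept + X @ beta
        return pd.Series(1.0 / (1.0 + np.exp(-z)), index=oh.signals.columns)


def select_markers(
    oh: OneHotMatrix,
    labels: Mapping[str, str],
    k: int,
    candidate_regions: Optional[Sequence[str]] = None,
    p_adj: Optional[Mapping[str, float]] = None,
    C: float = 1.0,
    seed: Optional[int] = None,
) -> MarkerModel:
    """Rank regions by an L2-regularised logistic fit and keep the top k.

    Regions are ranked by the absolute standardised coefficient
    (|coef| x feature SD) of a single multivariate fit on the one-hot
    signals, ties broken by lower screening ``p_adj`` then by region key;
    the model is then refit on the winning k regions. Regularisation
    absorbs perfect separation. Deterministic given the inputs.
    """
    from sklearn.linear_model import LogisticRegression

    region_keys = (
        list(candidate_regions)
        if candidate_regions is not None
        else list(oh.signals.index)
    )
    if k > len(region_keys):
        raise ValidationError(
            f"k={k} exceeds the {len(region_keys)} candidate regions"
        )
    samples = list(oh.signals.columns)
    y = np.array([1 if labels[s] == "case" else 0 for s in samples])
    if y.min() == y.max():
        raise ValidationError("both case and control samples required")

    X = oh.signals.loc[region_keys, samples].to_numpy(dtype=float).T
    model = LogisticRegression(C=C, solver="lbfgs", max_iter=2000)
    model.fit(X, y)
    importance = np.abs(model.coef_[0]) * X.std(axis=0)
    padj = [
        (p_adj or {}).get(r, np.inf) for r in region_keys
    ]
    ranking = pd.DataFrame(
        {
            "region": region_keys,
            "importance": importance,
            "p_adj": padj,
        }
    ).sort_values(
        ["importance", "p_adj", "region"], ascending=[False, True, True]
    )
    selected = list(ranking["region"].head(k))

    Xk = oh.signals.loc[selected, samples].to_numpy(dtype=float).T
    refit = LogisticRegression(C=C, solver="lbfgs", max_iter=2000)
    refit.fit(Xk, y)
    return MarkerModel(
        selected_regions=selected,
        intercept=float(refit.intercept_[0]),
        coefficients={r: float(c) for r, c in zip(selected, refit.coef_[0])},
        n_training=len(samples),
        seed=seed,
        C=C,
        ranking=ranking.reset_index(drop=True),
    )
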