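"""qMSP readout interpretation: QC gating, marker calling, panel
combination, risk scoring and cutoff calibration.

A sample first passes the reference-gene gate (ACTB Ct <= 34.8 and, when
measured, plasma cfDNA >= 0.9 ng/mL — thresholds established on clinical
material; both inclusive). Each marker is then called positive when its
Ct is at or below the marker's cutoff; a well that never amplified is
negative (no methylated template), a well that was not run is invalid.
The panel combines marker calls by the parallel (OR) rule — positive if
any valid marker is positive — which maximises sensitivity; a logistic
combination over Ct features is available as the alternative.

The methylation risk score is ``45 − ΔCt`` with ``ΔCt = marker Ct −
ACTB Ct`` and undetected markers at the 45-cycle ceiling; the panel
score is the maximum over markers, so more methylation means a higher
score.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import (
    CallerConfig,
    PanelCall,
    QmspRecord,
    ValidationError,
)

__all__ = [
    "qc_gate",
    "call_marker",
    "combine_parallel",
    "combine_logistic",
    "risk_score",
    "call_sample",
    "call_cohort",
    "calibrate_cutoffs",
    "fit_logistic_combination",
    "marker_features",
]


def qc_gate(r: QmspRecord, cfg: CallerConfig) -> tuple[bool, str]:
    """Sample-level quality gate.

    Valid iff the reference ACTB Ct is present and <= ``actb_max``
    (inclusive) and, when a cfDNA concentration was recorded, it is
    >= ``cfdna_min``. The reason names the first failing rule.
    """
    if r.actb_ct is None:
        return False, "reference_gene_missing"
    if r.actb_ct > cfg.actb_max:
        return False, "reference_gene"
    if r.cfdna_ng_ml is not None and r.cfdna_ng_ml < cfg.cfdna_min:
        return False, "cfdna"
    return True, "ok"


def call_marker(r: QmspRecord, marker: str, cfg: CallerConfig) -> str:
    """Positive / negative / invalid call for one marker well.

    Positive iff a Ct is present and <= the marker cutoff (inclusive,
    mirroring the reference-gene rule); undetected (no amplification)
    is negative; a well that was not run is invalid.
    """
    if marker not in cfg.marker_cutoffs:
        raise ValidationError(f"unknown marker {marker!r}")
    if marker not in r.marker_cts:
        return "invalid"
    ct = r.marker_cts[marker]
    if ct is None:
        return "negative"
    return "positive" if ct <= cfg.marker_cutoffs[marker] else "negative"


def combine_parallel(calls: Mapping[str, str]) -> str:
    """Parallel (OR) combination over valid marker calls.

    Positive if any valid call is positive; negative if all valid calls
    are negative; no_call when no marker produced a valid call.
    """
    valid = [c for c in calls.values() if c in ("positive", "negative")]
    if not valid:
        return "no_call"
    return "positive" if "positive" in valid else "negative"


def marker_features(r: QmspRecord, cfg: CallerConfig) -> np.ndarray:
    """Reference-adjusted numeric features, one per configured marker.

    Feature = marker Ct − ACTB Ct, with undetected markers at the cycle
    ceiling; lower values mean more methylated template.
    """
    if r.actb_ct is None:
        raise ValidationError(f"{r.sample_id}: ACTB Ct required for features")
    feats = []
    for marker in cfg.markers:
        ct = r.marker_cts.get(marker)
        if ct is None:
            ct = cfg.ct_ceiling
        feats.append(ct - r.actb_ct)
    return np.asarray(feats, dtype=float)


def combine_logistic(r: QmspRecord, cfg: CallerConfig) -> float:
    """Logistic-model probability of cancer from the marker features."""
    if cfg.logistic_coefs is None or cfg.logistic_intercept is None:
        raise ValidationError("logistic combination requires fitted coefficients")
    x = marker_features(r, cfg)
    beta = np.asarray([cfg.logistic_coefs[m] for m in cfg.markers])
    z = cfg.logistic_intercept + float(beta @ x)
    return 1.0 / (1.0 + math.exp(-z))


def risk_score(r: QmspRecord, cfg: CallerConfig) -> float:
    """Methylation risk score ``45 − ΔCt``, maximised over markers.

    With every marker undetected the score floors at the ACTB Ct itself
    (45 − (45 − actb)). In ``marker_only`` mode the score is
    ``45 − marker Ct`` without reference adjustment.
    """
    per_marker = []
    for marker in cfg.markers:
        ct = r.marker_cts.get(marker)
        if ct is None:
            ct = cfg.ct_ceiling
        if cfg.risk_score_mode == "marker_only":
            per_marker.append(cfg.ct_ceiling - ct)
        else:
            if r.actb_ct is None:
                raise ValidationError(
                    f"{r.sample_id}: ACTB Ct required for delta-Ct risk score"
                )
            per_marker.append(cfg.ct_ceiling - (ct - r.actb_ct))
    return max(per_marker)


def call_sample(r: QmspRecord, cfg: CallerConfig) -> PanelCall:
    """Full interpretation of one record: QC, marker calls, panel call,
    risk score and (when configured) model probability."""
    valid, reason = qc_gate(r, cfg)
    if not valid:
        return PanelCall(
            sample_id=r.sample_id,
            qc_valid=False,
            qc_reason=reason,
            marker_calls={m: "invalid" for m in cfg.markers},
            panel_call="no_call",
        )
    calls = {m: call_marker(r, m, cfg) for m in cfg.markers}
    if cfg.combination == "logistic":
        prob = combine_logistic(r, cfg)
        panel = "positive" if prob >= 0.5 else "negative"
    else:
        prob = None
        panel = combine_parallel(calls)
    return PanelCall(
        sample_id=r.sample_id,
        qc_valid=True,
        qc_reason="ok",
        marker_calls=calls,
        panel_call=panel,
        risk_score=risk_score(r, cfg),
        model_probability=prob,
    )


def call_cohort(records: Sequence[QmspRecord], cfg: CallerConfig) -> list[PanelCall]:
    return [call_sample(r, cfg) for r in records]


def calibrate_cutoffs(
    training: Sequence[QmspRecord],
    labels: Mapping[str, str],
    target_specificity: float = 0.95,
    base: Optional[CallerConfig] = None,
) -> CallerConfig:
    """Choose per-marker Ct cutoffs from control samples.

    For each marker the cutoff is the largest Ct value at which the
    marker-level specificity among QC-valid training controls stays at or
    above ``target_specificity`` (a control is a false positive when it
    amplified at or below the cutoff). With no control amplification the
    cutoff is the cycle ceiling — any amplification calls positive; when
    even the earliest control Ct must be excluded, the cutoff sits just
    below it. Deterministic given the training set.
    """
    cfg = base if base is not None else CallerConfig()
    if not 0 < target_specificity <= 1:
        raise ValidationError("target_specificity must be in (0, 1]")
    valid = [r for r in training if qc_gate(r, cfg)[0]]
    controls = [r for r in valid if labels[r.sample_id] == "control"]
    cases = [r for r in valid if labels[r.sample_id] == "case"]
    if not controls:
        raise ValidationError("cutoff calibration requires control samples")
    if not cases:
        raise ValidationError("cutoff calibration requires case samples")

    cutoffs: dict[str, float] = {}
    for marker in cfg.markers:
        control_cts = sorted(
            r.marker_cts[marker]
            for r in controls
            if r.marker_cts.get(marker) is not None
        )
        n = len(controls)
        # candidate cutoffs, largest first: the ceiling, then just below
        # each control Ct (comparison is inclusive, so excluding a control
        # at Ct c needs a cutoff strictly below c)
        candidates = [cfg.ct_ceiling] + [
            np.nextafter(ct, 0.0) for ct in sorted(set(control_cts), reverse=True)
        ]
        chosen = candidates[-1]
        for cand in candidates:
            n_fp = sum(ct <= cand for ct in control_cts)
            if (n - n_fp) / n >= target_specificity:
                chosen = cand
                break
        cutoffs[marker] = float(chosen)

    calibrated = CallerConfig(
        marker_cutoffs=cutoffs,
        ct_ceiling=cfg.ct_ceiling,
        actb_max=cfg.actb_max,
        cfdna_min=cfg.cfdna_min,
        combination=cfg.combination,
        risk_score_mode=cfg.risk_score_mode,
    )
    return calibrated


def fit_logistic_combination(
    training: Sequence[QmspRecord],
    labels: Mapping[str, str],
    base: Optional[CallerConfig] = None,
    C: float = 1.0,
) -> CallerConfig:
    """Fit the logistic panel combination on reference-adjusted Ct
    features (L2-regularised; cases coded 1)."""
    from sklearn.linear_model import LogisticRegression

    cfg = base if base is not None else CallerConfig()
    valid = [r for r in training if qc_gate(r, cfg)[0]]
    if not valid:
        raise ValidationError("no QC-valid training records")
    X = np.vstack([marker_features(r, cfg) for r in valid])
    y = np.array([1 if labels[r.sample_id] == "case" else 0 for r in valid])
    if y.min() == y.max():
        raise ValidationError("both classes required to fit the combination")
    model = LogisticRegression(C=C, solver="lbfgs", max_iter=1000)
    model.fit(X, y)
    return CallerConfig(
        marker_cutoffs=dict(cfg.marker_cutoffs),
        ct_ceiling=cfg.ct_ceiling,
        actb_max=cfg.actb_max,
        cfdna_min=cfg.cfdna_min,
        combination="logistic",
        logistic_intercept=float(model.intercept_[0]),
        logistic_coefs={
            m: float(c) for m, c in zip(cfg.markers, model.coef_[0])
        },
        risk_score_mode=cfg.risk_score_mode,
    )
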