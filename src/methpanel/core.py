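"""Shared domain types for the cfDNA methylation marker panel pipeline.

The pipeline models a plasma methylated-DNA-marker (MDM) test for
esophageal cancer: region-level methylation matrices feed marker
discovery, and per-sample qMSP readouts (a reference-gene Ct plus one Ct
per marker) feed panel calling and diagnostic evaluation.

Conventions
-----------
* Genomic coordinates are 0-based, half-open throughout.
* Methylation levels ("beta" values) live in [0, 1]; NaN marks missing.
* A qMSP marker that never amplified is *undetected* — represented by
  ``None`` in :attr:`QmspRecord.marker_cts`, never by an in-range Ct.
  A marker absent from the mapping means the well was not run.
* The numeric stand-in for an undetected marker, where one is required
  (risk scores, logistic features, ROC), is the cycle ceiling (45).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: Marker names of the 3-MDM panel used as defaults throughout.
PANEL_MARKERS: tuple[str, ...] = ("Septin9", "Epo", "MT1A")

#: Maximum qPCR cycle number; also the numeric stand-in for "undetected".
CT_CEILING: float = 45.0

#: Reference-gene (ACTB) QC threshold: sample valid iff ACTB Ct <= this.
ACTB_MAX_CT: float = 34.8

#: Minimum plasma cfDNA concentration (ng/mL) for a valid sample.
CFDNA_MIN_NG_ML: float = 0.9


class ValidationError(ValueError):
    """Raised when an input object violates a documented invariant."""


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValidationError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: "
                "start must be < end"
            )

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @classmethod
    def from_key(cls, key: str) -> "GenomicRegion":
        try:
            chrom, span = key.rsplit(":", 1)
            start, end = span.split("-")
            return cls(chrom, int(start), int(end))
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"malformed region key {key!r}") from exc

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicRegion") -> Optional[int]:
        """End-to-start distance to ``other``; 0 if overlapping/abutting,
        None if on different chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass(frozen=True)
class ProbeRecord:
    """An array probe located on the genome (e.g. 450K or GoldenGate)."""

    probe_id: str
    platform: str
    region: GenomicRegion


@dataclass
class MethylMatrix:
    """Region x sample methylation levels with per-sample group labels.

    ``values`` is a DataFrame indexed by region key ("chrom:start-end")
    with one column per sample; ``groups`` maps sample_id -> group label.
    """

    regions: list[GenomicRegion]
    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        keys = [r.key for r in self.regions]
        if list(self.values.index) != keys:
            raise ValidationError("values index must match region keys")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValidationError(f"samples without group label: {missing[:5]}")
        arr = self.values.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            i, j = np.argwhere(bad & ~np.isnan(arr))[0]
            raise ValidationError(
                f"methylation level outside [0, 1] at region "
                f"{self.values.index[i]}, sample {self.values.columns[j]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


@dataclass
class QmspRecord:
    """One participant's qMSP readout.

    ``marker_cts`` maps marker name to a Ct in (0, ceiling], or ``None``
    for "no amplification" (undetected). A marker missing from the map
    means the assay was not run for that well.
    """

    sample_id: str
    group: str = ""
    stage: str = ""
    actb_ct: Optional[float] = None
    marker_cts: dict[str, Optional[float]] = field(default_factory=dict)
    cfdna_ng_ml: Optional[float] = None

    def __post_init__(self) -> None:
        for marker, ct in self.marker_cts.items():
            if ct is not None and not (0 < ct <= CT_CEILING):
                raise ValidationError(
                    f"{self.sample_id}: Ct for {marker} must be in "
                    f"(0, {CT_CEILING}], got {ct}"
                )
        if self.actb_ct is not None and not (0 < self.actb_ct <= CT_CEILING):
            raise ValidationError(
                f"{self.sample_id}: ACTB Ct must be in (0, {CT_CEILING}], "
                f"got {self.actb_ct}"
            )
        if self.cfdna_ng_ml is not None and self.cfdna_ng_ml < 0:
            raise ValidationError(
                f"{self.sample_id}: cfDNA concentration must be >= 0"
            )

    @property
    def is_case(self) -> bool:
        return self.group.startswith("ec")


@dataclass
class PanelCall:
    """Per-marker and combined positivity plus risk score for one sample."""

    sample_id: str
    qc_valid: bool
    qc_reason: str
    marker_calls: dict[str, str]  # marker -> positive | negative | invalid
    panel_call: str  # positive | negative | no_call
    risk_score: Optional[float] = None
    model_probability: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.qc_valid and self.panel_call != "no_call":
            raise ValidationError(
                f"{self.sample_id}: QC-invalid sample must be no_call"
            )


@dataclass
class CallerConfig:
    """Interpretation parameters for qMSP panel calling."""

    marker_cutoffs: dict[str, float] = field(
        default_factory=lambda: {m: CT_CEILING for m in PANEL_MARKERS}
    )
    ct_ceiling: float = CT_CEILING
    actb_max: float = ACTB_MAX_CT
    cfdna_min: float = CFDNA_MIN_NG_ML
    combination: str = "parallel"  # parallel | logistic
    logistic_intercept: Optional[float] = None
    logistic_coefs: Optional[dict[str, float]] = None
    # risk-score ΔCt uses the reference gene by default; "marker_only"
    # scores 45 - marker Ct without reference adjustment.
    risk_score_mode: str = "delta_ct"

    def __post_init__(self) -> None:
        for marker, cutoff in self.marker_cutoffs.items():
            if cutoff > self.ct_ceiling:
                raise ValidationError(
                    f"cutoff for {marker} exceeds ct_ceiling"
                )
        if not self.actb_max < self.ct_ceiling:
            raise ValidationError("actb_max must be below ct_ceiling")
        if self.combination not in ("parallel", "logistic"):
            raise ValidationError(f"unknown combination {self.combination!r}")

    @property
    def markers(self) -> list[str]:
        return list(self.marker_cutoffs)


@dataclass(frozen=True)
class ConfusionCounts:
    """A 2x2 diagnostic table: disease truth vs test call."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive_truth(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative_truth(self) -> int:
        return self.fp + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )

    def as_dict(self) -> dict[str, int]:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching how clinical percentages are
    conventionally printed (0.86485 -> 86.49 at 2 dp on the % scale)."""
    if math.isnan(x):
        return x
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def as_percent(p: float, ndigits: int = 2) -> float:
    """Proportion -> percentage with half-up rounding."""
    return round_half_up(100.0 * p, ndigits)
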