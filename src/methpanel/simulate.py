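"""Cohort and matrix simulators.

Two generators stand in for the study cohorts so every downstream stage
is testable without the deposited data:

* :func:`generate_discovery_data` emits a region x sample methylation
  matrix shaped like the discovery phase — hypermethylated tumor regions
  planted over a quiet background, adjacent-normal tissue at background,
  a low white-blood-cell compartment, and noisy plasma in which only a
  fraction of case samples carry the tumor signal.
* :func:`generate_qmsp_cohort` emits per-participant qMSP records with
  stage-dependent marker-detection probabilities, truncated-normal Ct
  values for detected markers, an ACTB reference Ct, and a cfDNA
  concentration.

Default parameters encode the clinical cohort structure (group sizes and
per-stratum panel positivity) so a simulation at the defaults reproduces
the trial's operating characteristics up to binomial noise. One
top-level seed drives everything; per-group substreams are spawned
deterministically, so identical seeds give identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    CT_CEILING,
    GenomicRegion,
    MethylMatrix,
    PANEL_MARKERS,
    QmspRecord,
    ValidationError,
)

__all__ = [
    "DiscoverySpec",
    "CohortSpec",
    "generate_discovery_data",
    "generate_qmsp_cohort",
    "solve_marker_detection",
    "STAGE_GROUPS",
    "CLINICAL_GROUP_SIZES",
    "CLINICAL_POSITIVE_RATES",
]

#: EC stage strata, in AJCC order, plus the unknown-stage stratum.
STAGE_GROUPS: tuple[str, ...] = (
    "ec_stage0",
    "ec_stage1",
    "ec_stage2",
    "ec_stage3",
    "ec_stage4",
    "ec_unknown",
)

#: Clinical-cohort group sizes (cases by stage; controls by category).
CLINICAL_GROUP_SIZES: dict[str, int] = {
    "ec_stage0": 32,
    "ec_stage1": 106,
    "ec_stage2": 111,
    "ec_stage3": 204,
    "ec_stage4": 117,
    "ec_unknown": 71,
    "benign": 298,
    "healthy": 292,
    "other:lung": 28,
    "other:liver": 19,
    "other:colorectal": 51,
    "other:breast": 30,
    "other:gastric": 70,
}

#: Panel positivity rate per group in the clinical cohort: per-stage
#: sensitivity for cases, (1 - specificity) for control categories.
CLINICAL_POSITIVE_RATES: dict[str, float] = {
    "ec_stage0": 18 / 32,
    "ec_stage1": 82 / 106,
    "ec_stage2": 96 / 111,
    "ec_stage3": 183 / 204,
    "ec_stage4": 110 / 117,
    "ec_unknown": 59 / 71,
    "benign": 1 - 278 / 298,
    "healthy": 1 - 284 / 292,
    "other:lung": 0.0,
    "other:liver": 1 - 15 / 19,
    "other:colorectal": 1 - 29 / 51,
    "other:breast": 0.0,
    "other:gastric": 1 - 49 / 70,
}


def solve_marker_detection(
    panel_rate: float, n_markers: int = len(PANEL_MARKERS)
) -> float:
    """Per-marker detection probability reproducing a target panel
    positivity under the OR rule with independent, exchangeable markers:
    solves ``1 - (1 - p)^m = panel_rate``."""
    if not 0 <= panel_rate <= 1:
        raise ValidationError("panel_rate must be in [0, 1]")
    return 1.0 - (1.0 - panel_rate) ** (1.0 / n_markers)


def _check_prob(name: str, value: float) -> None:
    if not 0 <= value <= 1:
        raise ValidationError(f"{name} must be in [0, 1], got {value}")


# ---------------------------------------------------------------------------
# discovery-phase matrix
# ---------------------------------------------------------------------------

@dataclass
class DiscoverySpec:
    """Generative parameters for a discovery-phase methylation matrix.

    Sample sizes default to the discovery-phase composition (108 tumor,
    107 adjacent-normal, 249 WBC; 56 case and 107 control plasma).
    ``noise_conc`` is the concentration of the beta noise around each
    compartment mean (higher = tighter); 20 gives an SD of ~0.065 at a
    mean of 0.1, a realistic array/WGBS region-level spread.
    """

    n_regions: int = 500
    n_dmr: int = 10
    n_tumor: int = 108
    n_adjacent: int = 107
    n_wbc: int = 249
    n_plasma_case: int = 56
    n_plasma_control: int = 107
    base_beta: float = 0.10
    delta_planted: float = 0.40
    wbc_beta: float = 0.05
    noise_conc: float = 20.0
    plasma_signal_rate: float = 0.80
    seed: int = 0

    def validate(self) -> None:
        for f in fields(self):
            if f.name.startswith("n_") and getattr(self, f.name) < 0:
                raise ValidationError(f"{f.name} must be >= 0")
        if self.n_dmr > self.n_regions:
            raise ValidationError("n_dmr must be <= n_regions")
        for name in ("base_beta", "wbc_beta", "plasma_signal_rate"):
            _check_prob(name, getattr(self, name))
        if not 0 <= self.base_beta + self.delta_planted <= 1:
            raise ValidationError(
                "base_beta + delta_planted must lie in [0, 1], got "
                f"{self.base_beta + self.delta_planted}"
            )
        if self.noise_conc <= 0:
            raise ValidationError("noise_conc must be > 0")


def _beta_draw(rng: np.random.Generator, mean: np.ndarray, conc: float) -> np.ndarray:
    """Beta noise with given mean and concentration; means clipped away
    from {0, 1} so the distribution stays proper."""
    mu = np.clip(mean, 1e-3, 1 - 1e-3)
    return rng.beta(mu * conc, (1 - mu) * conc)


def _random_regions(rng: np.random.Generator, n: int, width: int = 150) -> list[GenomicRegion]:
    chroms = rng.integers(1, 23, size=n)
    starts = rng.integers(10_000, 200_000_000, size=n)
    regions = [
        GenomicRegion(f"chr{c}", int(s), int(s) + width)
        for c, s in zip(chroms, starts)
    ]
    return regions


def generate_discovery_data(
    spec: DiscoverySpec,
) -> tuple[MethylMatrix, list[str]]:
    """Simulate a discovery matrix; returns (matrix, planted region keys).

    Planted regions are hypermethylated in tumor (mean ``base_beta +
    delta_planted`` vs ``base_beta`` in adjacent normal) and quiet in
    WBC (``wbc_beta``); plasma runs at the WBC background except that a
    ``plasma_signal_rate`` fraction of case samples carry a visible
    tumor-derived elevation at each planted region. Byte-identical
    output for identical specs.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_regions, rng_tissue, rng_plasma = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    regions = _random_regions(rng_regions, spec.n_regions)
    planted_idx = (
        rng_regions.choice(spec.n_regions, size=spec.n_dmr, replace=False)
        if spec.n_dmr
        else np.array([], dtype=int)
    )
    planted = np.zeros(spec.n_regions, dtype=bool)
    planted[planted_idx] = True

    groups: dict[str, str] = {}
    columns: dict[str, np.ndarray] = {}

    def add_samples(prefix: str, group: str, n: int, mean: np.ndarray, rng):
        for i in range(n):
            sid = f"{prefix}{i:03d}"
            groups[sid] = group
            columns[sid] = _beta_draw(rng, mean, spec.noise_conc)

    base = np.full(spec.n_regions, spec.base_beta)
    tumor_mean = np.where(planted, spec.base_beta + spec.delta_planted, base)
    wbc_mean = np.full(spec.n_regions, spec.wbc_beta)

    add_samples("tumor_", "tumor", spec.n_tumor, tumor_mean, rng_tissue)
    add_samples("adjacent_", "adjacent", spec.n_adjacent, base, rng_tissue)
    add_samples("wbc_", "wbc", spec.n_wbc, wbc_mean, rng_tissue)

    # plasma: leukocyte-dominated background; cases intermittently carry
    # a tumor-derived elevation at planted regions
    signal_mean = np.where(
        planted,
        np.clip(spec.wbc_beta + spec.delta_planted, 0, 1),
        wbc_mean,
    )
    for i in range(spec.n_plasma_case):
        sid = f"plasma_case_{i:03d}"
        groups[sid] = "plasma_case"
        carries = rng_plasma.random(spec.n_regions) < spec.plasma_signal_rate
        mean = np.where(planted & carries, signal_mean, wbc_mean)
        columns[sid] = _beta_draw(rng_plasma, mean, spec.noise_conc)
    add_samples(
        "plasma_control_", "plasma_control", spec.n_plasma_control,
        wbc_mean, rng_plasma,
    )

    values = pd.DataFrame(columns, index=[r.key for r in regions])
    matrix = MethylMatrix(regions=regions, values=values, groups=groups)
    planted_keys = [regions[i].key for i in sorted(planted_idx)]
    return matrix, planted_keys


# ---------------------------------------------------------------------------
# qMSP cohort
# ---------------------------------------------------------------------------

def _default_p_detect() -> dict[tuple[str, str], float]:
    out = {}
    for group, rate in CLINICAL_POSITIVE_RATES.items():
        p = solve_marker_detection(rate)
        for marker in PANEL_MARKERS:
            out[(group, marker)] = p
    return out


@dataclass
class CohortSpec:
    """Generative parameters for a qMSP cohort.

    Defaults encode the clinical validation cohort: the printed group
    sizes and, through :func:`solve_marker_detection`, per-marker
    detection probabilities that reproduce each stratum's printed panel
    positivity under the OR rule. Detected-marker Ct values are normal
    (mean 33, SD 2.5 cycles — typical plasma qMSP late-amplification
    territory) truncated at the 45-cycle ceiling; the ACTB reference
    runs at 29 +/- 1.5 cycles. QC failures are off by default because
    the trial's denominators match its cohort sizes.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: dict(CLINICAL_GROUP_SIZES)
    )
    p_detect: dict[tuple[str, str], float] = field(
        default_factory=_default_p_detect
    )
    markers: tuple[str, ...] = PANEL_MARKERS
    ct_mu_pos: float = 33.0
    ct_sd_pos: float = 2.5
    actb_mu: float = 29.0
    actb_sd: float = 1.5
    cfdna_mu_log: float = 1.6  # ~5 ng/mL median
    cfdna_sd_log: float = 0.5
    ct_ceiling: float = CT_CEILING
    actb_max: float = 34.8
    qc_fail_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for group, n in self.n_per_group.items():
            if n < 0:
                raise ValidationError(f"n_per_group[{group!r}] must be >= 0")
        known = set(self.n_per_group)
        for (group, marker), p in self.p_detect.items():
            if group not in known:
                raise ValidationError(
                    f"p_detect references unknown group {group!r}"
                )
            if marker not in self.markers:
                raise ValidationError(
                    f"p_detect references unknown marker {marker!r}"
                )
            _check_prob(f"p_detect[{group}, {marker}]", p)
        _check_prob("qc_fail_rate", self.qc_fail_rate)
        if not self.ct_mu_pos < self.ct_ceiling:
            raise ValidationError("ct_mu_pos must be below ct_ceiling")
        if self.ct_sd_pos <= 0 or self.actb_sd <= 0:
            raise ValidationError("Ct standard deviations must be > 0")


def _stage_of(group: str) -> str:
    if group.startswith("ec_"):
        return group.removeprefix("ec_").replace("stage", "stage_")
    return ""


def generate_qmsp_cohort(spec: CohortSpec) -> list[QmspRecord]:
    """Simulate one qMSP record per participant.

    Marker wells amplify with probability ``p_detect[(group, marker)]``
    (default 0 for unlisted pairs); detected Ct ~ Normal(ct_mu_pos,
    ct_sd_pos) truncated to (0, ct_ceiling]. A ``qc_fail_rate`` fraction
    of samples receive an ACTB Ct above the QC threshold. Identical
    specs give identical cohorts.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    group_order = sorted(spec.n_per_group)
    streams = {
        g: np.random.default_rng(s)
        for g, s in zip(group_order, ss.spawn(len(group_order)))
    }

    a_ct = (0.0 - spec.ct_mu_pos) / spec.ct_sd_pos
    b_ct = (spec.ct_ceiling - spec.ct_mu_pos) / spec.ct_sd_pos
    markers = list(spec.markers)

    records: list[QmspRecord] = []
    for group in group_order:
        rng = streams[group]
        n = spec.n_per_group[group]
        if n == 0:
            continue
        qc_fail = rng.random(n) < spec.qc_fail_rate
        actb = np.clip(
            rng.normal(spec.actb_mu, spec.actb_sd, size=n), 0.01, spec.actb_max
        )
        actb[qc_fail] = rng.uniform(
            spec.actb_max + 0.1, spec.ct_ceiling, size=int(qc_fail.sum())
        )
        p = np.array([spec.p_detect.get((group, m), 0.0) for m in markers])
        detected = rng.random((n, len(markers))) < p
        cts = stats.truncnorm.rvs(
            a_ct, b_ct, loc=spec.ct_mu_pos, scale=spec.ct_sd_pos,
            size=(n, len(markers)), random_state=rng,
        )
        cfdna = np.exp(rng.normal(spec.cfdna_mu_log, spec.cfdna_sd_log, size=n))
        for i in range(n):
            marker_cts: dict[str, Optional[float]] = {
                m: (float(cts[i, j]) if detected[i, j] else None)
                for j, m in enumerate(markers)
            }
            records.append(
                QmspRecord(
                    sample_id=f"{group.replace(':', '_')}_{i:04d}",
                    group=group,
                    stage=_stage_of(group),
                    actb_ct=float(actb[i]),
                    marker_cts=marker_cts,
                    cfdna_ng_ml=float(cfdna[i]),
                )
            )
    return records
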