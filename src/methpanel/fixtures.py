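"""Reconstructed count tables from the trial's printed summary numbers.

The raw per-participant data are not redistributable, but every headline
metric traces back to small integer tables that are recoverable exactly
from the printed percentages and group sizes. This module rebuilds them:

* each printed percentage with a known denominator is inverted to the
  unique integer numerator that rounds (half-up, 2 dp) back to the
  printed value — the build fails loudly if no or multiple integers fit;
* the model-verification 2x2 table is recovered by brute-force search
  over tables with the cohort's margins that reproduce the printed
  accuracy and kappa, taking the symmetric-error solution (|fp - fn|
  minimal) when rounding admits more than one;
* the treatment-monitoring pre/post score pairs are a deterministic
  stand-in with the published outcome frequencies (29 of 32 negative
  after surgery, 3 non-declining scores).

Everything here is deterministic and internally cross-checked (stratum
true positives sum to the overall true positives, margins match the
published cohort sizes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import ConfusionCounts, ValidationError, as_percent
from .evaluation import kappa

__all__ = ["FixtureSet", "build_fixtures", "count_from_percent"]


def count_from_percent(percent: float, n: int) -> int:
    """The unique integer x in [0, n] with 100*x/n rounding (half-up,
    2 dp) to ``percent``; raises if none or several fit."""
    hits = [x for x in range(n + 1) if as_percent(x / n) == round(percent, 2)]
    if len(hits) != 1:
        raise ValidationError(
            f"{percent}% of n={n} does not identify a unique count "
            f"(candidates: {hits})"
        )
    return hits[0]


def _solve_confusion(
    n_cases: int,
    n_controls: int,
    accuracy_pct: float,
    kappa_2dp: float,
) -> ConfusionCounts:
    """Brute-force the 2x2 table with the given truth margins whose
    accuracy and kappa round to the printed values; symmetric-error
    tie-break (smallest |fp - fn|)."""
    hits: list[ConfusionCounts] = []
    for tp in range(n_cases + 1):
        for tn in range(n_controls + 1):
            c = ConfusionCounts(tp, n_controls - tn, n_cases - tp, tn)
            if as_percent((tp + tn) / c.total) != round(accuracy_pct, 2):
                continue
            if round(kappa(c), 2) == round(kappa_2dp, 2):
                hits.append(c)
    if not hits:
        raise ValidationError(
            "no confusion table matches the printed accuracy and kappa"
        )
    hits.sort(key=lambda c: (abs(c.fp - c.fn), c.tp))
    return hits[0]


@dataclass
class FixtureSet:
    """Named count tables plus the treatment-monitoring pairs."""

    tables: dict[str, ConfusionCounts]
    stage_counts: dict[str, tuple[int, int]]  # stage -> (tp, n)
    other_cancer_counts: dict[str, tuple[int, int]]  # type -> (tn, n)
    post_op_pairs: list[tuple[float, float, str]]  # (pre, post, post_call)

    def to_json_dict(self) -> dict:
        return {
            "tables": {k: v.as_dict() for k, v in self.tables.items()},
            "stage_counts": {
                k: {"tp": tp, "n": n} for k, (tp, n) in self.stage_counts.items()
            },
            "other_cancer_counts": {
                k: {"tn": tn, "n": n}
                for k, (tn, n) in self.other_cancer_counts.items()
            },
            "post_op_pairs": [
                {"pre_score": pre, "post_score": post, "post_call": call}
                for pre, post, call in self.post_op_pairs
            ],
        }


# printed operating characteristics and group sizes of the clinical cohort
_N_EC = 641
_N_CONTROLS = 590  # benign 298 + healthy 292; other cancers tallied apart
_STAGE_SENS_PCT = {
    "stage0": (56.25, 32),
    "stageI": (77.36, 106),
    "stageII": (86.49, 111),  # 86.69 also appears in print; 96/111 is consistent
    "stageIII": (89.71, 204),
    "stageIV": (94.02, 117),
}
_N_STAGE_UNKNOWN = 71
_OTHER_CANCER_SPEC_PCT = {
    "lung": (100.00, 28),
    "breast": (100.00, 30),
    "liver": (78.95, 19),
    "colorectal": (56.86, 51),
    "gastric": (70.00, 70),
}


def build_fixtures() -> FixtureSet:
    """Rebuild every published count table; deterministic."""
    # overall clinical cohort: PPV 548/576, NPV 562/655
    clinical_overall = ConfusionCounts(tp=548, fp=576 - 548, fn=641 - 548,
                                       tn=562)
    if clinical_overall.total != _N_EC + _N_CONTROLS:
        raise ValidationError("clinical_overall margins inconsistent")

    # per-stage true positives from printed sensitivities
    stage_counts: dict[str, tuple[int, int]] = {}
    for stage, (pct, n) in _STAGE_SENS_PCT.items():
        stage_counts[stage] = (count_from_percent(pct, n), n)
    staged_tp = sum(tp for tp, _ in stage_counts.values())
    stage_counts["unknown"] = (clinical_overall.tp - staged_tp, _N_STAGE_UNKNOWN)
    if not 0 <= stage_counts["unknown"][0] <= _N_STAGE_UNKNOWN:
        raise ValidationError("stage true positives inconsistent with overall")

    # other-cancer specificity strata
    other_cancer: dict[str, tuple[int, int]] = {}
    for cancer, (pct, n) in _OTHER_CANCER_SPEC_PCT.items():
        other_cancer[cancer] = (count_from_percent(pct, n), n)
    other_tn = sum(tn for tn, _ in other_cancer.values())
    other_n = sum(n for _, n in other_cancer.values())

    # all controls folded in (the Youden computation's denominator)
    clinical_with_other = ConfusionCounts(
        tp=clinical_overall.tp,
        fp=clinical_overall.fp + (other_n - other_tn),
        fn=clinical_overall.fn,
        tn=clinical_overall.tn + other_tn,
    )

    # model-verification cohort: 92 cases (87 EC + 5 HGIN), 205 controls
    model_verification = _solve_confusion(
        n_cases=92, n_controls=205, accuracy_pct=95.29, kappa_2dp=0.89
    )

    # high-risk groups: diagnosed (257 EC of 534), diagnosing (384 of 697)
    diagnosed = _table_from_sens_spec(85.21, 97.11, n_cases=257, n_controls=277)
    diagnosing = _table_from_sens_spec(85.68, 93.61, n_cases=384, n_controls=313)

    # treatment monitoring: 29/32 negative post-surgery, 3 non-declining
    # risk scores (one pre-operatively low already). Synthetic stand-in
    # pairs on the 45-minus-delta-Ct scale with those outcome counts.
    post_op_pairs: list[tuple[float, float, str]] = []
    for i in range(29):
        pre = 38.0 + 0.2 * i
        post_op_pairs.append((pre, pre - 9.0, "negative"))
    post_op_pairs.append((29.5, 30.0, "positive"))  # pre-op false negative
    post_op_pairs.append((40.0, 40.5, "positive"))
    post_op_pairs.append((41.0, 41.5, "positive"))

    fx = FixtureSet(
        tables={
            "clinical_overall": clinical_overall,
            "clinical_with_other_cancers": clinical_with_other,
            "model_verification": model_verification,
            "diagnosed": diagnosed,
            "diagnosing": diagnosing,
        },
        stage_counts=stage_counts,
        other_cancer_counts=other_cancer,
        post_op_pairs=post_op_pairs,
    )
    _self_check(fx)
    return fx


def _table_from_sens_spec(
    sens_pct: float, spec_pct: float, n_cases: int, n_controls: int
) -> ConfusionCounts:
    tp = count_from_percent(sens_pct, n_cases)
    tn = count_from_percent(spec_pct, n_controls)
    return ConfusionCounts(tp=tp, fp=n_controls - tn, fn=n_cases - tp, tn=tn)


def _self_check(fx: FixtureSet) -> None:
    co = fx.tables["clinical_overall"]
    if (co.tp, co.fp, co.fn, co.tn) != (548, 28, 93, 562):
        raise ValidationError("clinical_overall table drifted")
    if sum(tp for tp, _ in fx.stage_counts.values()) != co.tp:
        raise ValidationError("stage true positives do not sum to overall")
    if fx.tables["diagnosed"].total != 534:
        raise ValidationError("diagnosed group size mismatch")
    if fx.tables["diagnosing"].total != 697:
        raise ValidationError("diagnosing group size mismatch")
    n_neg = sum(1 for _, _, call in fx.post_op_pairs if call == "negative")
    if (n_neg, len(fx.post_op_pairs)) != (29, 32):
        raise ValidationError("post-operative outcome counts drifted")
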