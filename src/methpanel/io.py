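"""File readers and writers.

Formats: regions as BED (0-based half-open, taken verbatim), methylation
matrices as TSV keyed by "chrom:start-end", cohorts and calls as CSV
(an empty Ct cell means the well never amplified), metrics and fixtures
as JSON, run configuration as YAML. All writers are deterministic —
stable column order, fixed float formatting, UTF-8, "." decimal point —
and stamp a schema version comment where the format allows one.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .core import (
    CallerConfig,
    GenomicRegion,
    MethylMatrix,
    PanelCall,
    QmspRecord,
    ValidationError,
)

__all__ = [
    "SCHEMA_VERSION",
    "RunConfig",
    "read_bed",
    "write_bed",
    "read_methyl_matrix",
    "write_methyl_matrix",
    "read_qmsp_cohort",
    "write_qmsp_cohort",
    "write_calls",
    "read_calls",
    "write_metrics_json",
    "write_fixtures_json",
    "read_caller_config",
    "write_caller_config",
]

SCHEMA_VERSION = "1"
_FLOAT_FMT = "%.6g"

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# regions / BED
# ---------------------------------------------------------------------------

def read_bed(path: PathLike) -> list[GenomicRegion]:
    regions = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValidationError(f"{path}:{lineno}: need >= 3 BED columns")
        try:
            region = GenomicRegion(parts[0], int(parts[1]), int(parts[2]))
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
        regions.append(region)
    return regions


def write_bed(regions: Sequence[GenomicRegion], path: PathLike) -> None:
    lines = [f"{r.chrom}\t{r.start}\t{r.end}" for r in regions]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# methylation matrices
# ---------------------------------------------------------------------------

def read_methyl_matrix(
    matrix_path: PathLike,
    bed_path: PathLike,
    samples_path: PathLike,
) -> MethylMatrix:
    """Assemble a matrix from its TSV + companion BED + sample sheet.

    Values outside [0, 1] are rejected with the offending cell named;
    region keys must match the BED regions exactly and sample ids must
    be covered by the sample sheet.
    """
    regions = read_bed(bed_path)
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    expected = [r.key for r in regions]
    if list(df.index) != expected:
        raise ValidationError(
            f"{matrix_path}: region keys do not match {bed_path}"
        )
    sheet = pd.read_csv(samples_path, comment="#")
    if not {"sample_id", "group"} <= set(sheet.columns):
        raise ValidationError(
            f"{samples_path}: sample sheet needs sample_id and group columns"
        )
    groups = dict(zip(sheet["sample_id"].astype(str), sheet["group"].astype(str)))
    arr = df.to_numpy(dtype=float)
    bad = np.argwhere(((arr < 0) | (arr > 1)) & ~np.isnan(arr))
    if len(bad):
        i, j = bad[0]
        raise ValidationError(
            f"{matrix_path}: value {arr[i, j]!r} outside [0, 1] at region "
            f"{df.index[i]}, sample {df.columns[j]}"
        )
    return MethylMatrix(regions=regions, values=df, groups=groups)


def write_methyl_matrix(
    m: MethylMatrix,
    matrix_path: PathLike,
    bed_path: PathLike,
    samples_path: PathLike,
) -> None:
    write_bed(m.regions, bed_path)
    with open(matrix_path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# methpanel matrix schema v{SCHEMA_VERSION}\n")
        m.values.to_csv(fh, sep="\t", float_format=_FLOAT_FMT, index_label="region")
    sheet = pd.DataFrame(
        {"sample_id": m.sample_ids, "group": [m.groups[s] for s in m.sample_ids]}
    )
    with open(samples_path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# methpanel sample sheet schema v{SCHEMA_VERSION}\n")
        sheet.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# qMSP cohorts
# ---------------------------------------------------------------------------

def _marker_columns(columns: Sequence[str]) -> list[str]:
    return [c.removeprefix("ct_") for c in columns if c.startswith("ct_")]


def read_qmsp_cohort(path: PathLike) -> list[QmspRecord]:
    """Read a cohort CSV; empty Ct cells become the undetected state."""
    df = pd.read_csv(path, comment="#", dtype={"sample_id": str})
    required = {"sample_id", "group", "actb_ct"}
    if not required <= set(df.columns):
        raise ValidationError(
            f"{path}: cohort CSV needs columns {sorted(required)}"
        )
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate sample_id {dup.iloc[0]!r}")
    markers = _marker_columns(df.columns)
    records = []
    for _, row in df.iterrows():
        marker_cts = {}
        for m in markers:
            v = row[f"ct_{m}"]
            marker_cts[m] = None if pd.isna(v) else float(v)
        for name, v in list(marker_cts.items()):
            if v is not None and v < 0:
                raise ValidationError(
                    f"{path}: negative Ct for {row['sample_id']}/{name}"
                )
        records.append(
            QmspRecord(
                sample_id=str(row["sample_id"]),
                group=str(row["group"]) if not pd.isna(row["group"]) else "",
                stage=(
                    str(row["stage"])
                    if "stage" in df.columns and not pd.isna(row["stage"])
                    else ""
                ),
                actb_ct=None if pd.isna(row["actb_ct"]) else float(row["actb_ct"]),
                marker_cts=marker_cts,
                cfdna_ng_ml=(
                    None
                    if "cfdna_ng_ml" not in df.columns
                    or pd.isna(row["cfdna_ng_ml"])
                    else float(row["cfdna_ng_ml"])
                ),
            )
        )
    return records


def write_qmsp_cohort(records: Sequence[QmspRecord], path: PathLike) -> None:
    markers: list[str] = []
    for r in records:
        for m in r.marker_cts:
            if m not in markers:
                markers.append(m)
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "group": r.group,
            "stage": r.stage,
            "actb_ct": r.actb_ct,
        }
        for m in markers:
            row[f"ct_{m}"] = r.marker_cts.get(m)
        row["cfdna_ng_ml"] = r.cfdna_ng_ml
        rows.append(row)
    df = pd.DataFrame(rows)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# methpanel cohort schema v{SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# calls and metrics
# ---------------------------------------------------------------------------

def write_calls(calls: Sequence[PanelCall], path: PathLike) -> None:
    markers: list[str] = []
    for c in calls:
        for m in c.marker_calls:
            if m not in markers:
                markers.append(m)
    rows = []
    for c in calls:
        row = {
            "sample_id": c.sample_id,
            "qc_valid": c.qc_valid,
            "qc_reason": c.qc_reason,
        }
        for m in markers:
            row[f"call_{m}"] = c.marker_calls.get(m, "invalid")
        row["panel_call"] = c.panel_call
        row["risk_score"] = c.risk_score
        row["probability"] = c.model_probability
        rows.append(row)
    df = pd.DataFrame(rows)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# methpanel calls schema v{SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_calls(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", dtype={"sample_id": str})


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def write_metrics_json(metrics_dict: dict, path: PathLike) -> None:
    payload = {"schema_version": SCHEMA_VERSION, **_jsonable(metrics_dict)}
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def write_fixtures_json(fixture_set, path: PathLike) -> None:
    payload = {"schema_version": SCHEMA_VERSION, **fixture_set.to_json_dict()}
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_RUNCONFIG_KEYS = {
    "seed",
    "log_level",
    "discovery",
    "cohort",
    "caller",
    "evaluation",
    "paths",
}


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run; round-trips via YAML."""

    seed: int = 0
    log_level: str = "INFO"
    discovery: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    caller: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _RUNCONFIG_KEYS - {"schema_version"}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        raw.pop("schema_version", None)
        return cls(**raw)

    def to_yaml(self, path: PathLike) -> None:
        payload = {"schema_version": SCHEMA_VERSION, **asdict(self)}
        Path(path).write_text(
            yaml.safe_dump(payload, sort_keys=True), encoding="utf-8"
        )


def read_caller_config(path: PathLike) -> CallerConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.pop("schema_version", None)
    if "logistic_coefs" in raw and raw["logistic_coefs"] is not None:
        raw["logistic_coefs"] = {
            str(k): float(v) for k, v in raw["logistic_coefs"].items()
        }
    return CallerConfig(**raw)


def write_caller_config(cfg: CallerConfig, path: PathLike) -> None:
    payload = {"schema_version": SCHEMA_VERSION, **asdict(cfg)}
    Path(path).write_text(
        yaml.safe_dump(payload, sort_keys=True), encoding="utf-8"
    )
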