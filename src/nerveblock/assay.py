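"""Thermal-latency assay primitives: baselines, censoring, %MPE, cohort filters.

The plantar and tail-flick tests measure how long an animal tolerates a
radiant heat stimulus before withdrawing the paw or tail.  Exposure is capped
at a per-assay cutoff (15 s plantar, 4 s tail-flick) to prevent tissue damage,
so readings at the cutoff are right-censored.  Analgesic effect at a time
point is expressed as the percent of maximal possible effect,

    %MPE = 100 * (post - pre) / (cutoff - pre),

clamped to [0, 100].  Animals whose trimmed baseline already reaches the
cutoff (profound neuropathy) have a non-positive denominator and are excluded
before any %MPE is computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssayConfig",
    "PLANTAR",
    "TAIL_FLICK",
    "MouseRecord",
    "LatencyMeasurement",
    "MPEValue",
    "trimmed_baseline",
    "compute_mpe",
    "classify_glycemic_status",
    "apply_sensory_exclusions",
    "read_cohort_csv",
    "read_measurements_csv",
]

#: glycemic inclusion thresholds (mmol/L fasting glucose)
DIABETIC_GLUCOSE_MMOL_L = 23.0
NONDIABETIC_GLUCOSE_MMOL_L = 8.0

_ASSAY_NAMES = ("plantar", "tail_flick")


@dataclass(frozen=True)
class AssayConfig:
    """One thermal assay: its censoring ceiling and stimulus intensity."""

    assay_name: str
    cutoff_s: float
    intensity_pct: float  # infrared intensity setting; metadata only

    def __post_init__(self) -> None:
        if self.assay_name not in _ASSAY_NAMES:
            raise ValueError(f"assay_name must be one of {_ASSAY_NAMES}, got {self.assay_name!r}")
        if not (math.isfinite(self.cutoff_s) and self.cutoff_s > 0):
            raise ValueError("cutoff_s must be positive and finite")


PLANTAR = AssayConfig("plantar", cutoff_s=15.0, intensity_pct=50.0)
TAIL_FLICK = AssayConfig("tail_flick", cutoff_s=4.0, intensity_pct=40.0)


@dataclass
class MouseRecord:
    """One animal: arm assignment, phenotyping covariates, inclusion status."""

    mouse_id: str
    condition: str  # "control" | "dm_pn"
    treatment: str  # "BH" | "LB"
    fasting_glucose_mmol_L: float
    weight_g: float
    baseline_latency_s: float  # trimmed mean of repeat readings, per assay
    status: str = "included"
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.baseline_latency_s < 0:
            raise ValueError("baseline_latency_s must be non-negative")
        if self.status == "excluded" and not self.exclusion_reason:
            raise ValueError("excluded records must carry a non-empty reason")


@dataclass(frozen=True)
class LatencyMeasurement:
    """One censored latency reading at a scheduled time since injection."""

    mouse_id: str
    t_min: float
    latency_s: float
    censored: bool  # True iff the stimulus was removed at the cutoff


@dataclass(frozen=True)
class MPEValue:
    mouse_id: str
    t_min: float
    mpe_pct: float


def trimmed_baseline(latencies: Sequence[float]) -> float:
    """Mean of the repeat readings lying within one SD of the overall mean.

    The trimming boundary is inclusive (|v - mean| <= sample SD), so at least
    the reading nearest the mean always survives; with identical readings the
    common value is returned unchanged.  Requires at least two repeats (the
    assay protocol takes three, 5 min apart).
    """
    values = np.asarray(latencies, dtype=float)
    if values.size < 2:
        raise ValueError("insufficient baseline repeats")
    if not np.all(np.isfinite(values)) or np.any(values < 0):
        raise ValueError("baseline repeats must be finite and non-negative")
    mean = values.mean()
    sd = values.std(ddof=1)
    keep = np.abs(values - mean) <= sd + 1e-9  # tolerance guards fp ties at the boundary
    assert keep.any(), "inclusive trimming cannot discard every repeat"
    return float(values[keep].mean())


def compute_mpe(pre: float, post: float, cutoff: float) -> float:
    """%MPE of one reading, clamped to [0, 100].

    A censored post-injection reading (post == cutoff) forces 100%.  Readings
    faster than baseline (hypoalgesic direction) clamp to 0 rather than going
    negative: the score measures block intensity, not hyperalgesia.
    """
    if pre >= cutoff:
        raise ValueError("baseline at or above cutoff — animal must be excluded upstream")
    if pre < 0 or not (0 <= post <= cutoff):
        raise ValueError("latencies must satisfy 0 <= pre < cutoff and 0 <= post <= cutoff")
    raw = 100.0 * (post - pre) / (cutoff - pre)
    return float(min(100.0, max(0.0, raw)))


def classify_glycemic_status(fasting_glucose_mmol_L: float) -> str:
    """Fasting-glucose phenotype: > 23 mmol/L diabetic, < 8 non-diabetic.

    The gap [8, 23] is reported as "indeterminate": such animals belong to
    neither study arm and are flagged rather than silently assigned.
    """
    g = fasting_glucose_mmol_L
    if not (isinstance(g, (int, float, np.floating, np.integer)) and math.isfinite(g)) or g < 0:
        raise ValueError("fasting glucose must be a finite non-negative number")
    if g > DIABETIC_GLUCOSE_MMOL_L:
        return "diabetic"
    if g < NONDIABETIC_GLUCOSE_MMOL_L:
        return "nondiabetic"
    return "indeterminate"


def apply_sensory_exclusions(
    cohort: Iterable[MouseRecord], config: AssayConfig
) -> tuple[list[MouseRecord], list[MouseRecord]]:
    """Partition a cohort by the censoring ceiling on the trimmed baseline.

    Animals whose baseline latency is at or above the cutoff have no %MPE
    denominator (neuropathy so severe the assay is saturated) and move to the
    excluded list with reason "neuropathy >= cutoff".  The partition is
    exhaustive and disjoint; records already excluded upstream stay excluded.
    """
    included: list[MouseRecord] = []
    excluded: list[MouseRecord] = []
    for rec in cohort:
        if rec.status == "excluded":
            excluded.append(rec)
        elif rec.baseline_latency_s >= config.cutoff_s:
            excluded.append(replace(rec, status="excluded", exclusion_reason="neuropathy >= cutoff"))
        else:
            included.append(rec)
    return included, excluded


# ---------------------------------------------------------------------------
# CSV interfaces

_COHORT_COLUMNS = [
    "mouse_id",
    "condition",
    "treatment",
    "glucose_mmol_L",
    "weight_g",
    "baseline_rep1_s",
    "baseline_rep2_s",
    "baseline_rep3_s",
]

_MEASUREMENT_COLUMNS = ["mouse_id", "t_min", "latency_s"]


class SchemaError(ValueError):
    """An input table does not match the expected column schema."""


def read_cohort_csv(path) -> list[MouseRecord]:
    """Read a cohort table and build records with trimmed baselines.

    Expected columns: mouse_id, condition, treatment, glucose_mmol_L,
    weight_g, baseline_rep1_s..baseline_rep3_s (UTF-8, header row, dot
    decimal separator).
    """
    df = pd.read_csv(path)
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort CSV missing columns: {missing}")
    if df.empty:
        raise SchemaError("cohort CSV contains no rows")
    records = []
    for row in df.itertuples(index=False):
        reps = [row.baseline_rep1_s, row.baseline_rep2_s, row.baseline_rep3_s]
        records.append(
            MouseRecord(
                mouse_id=str(row.mouse_id),
                condition=str(row.condition),
                treatment=str(row.treatment),
                fasting_glucose_mmol_L=float(row.glucose_mmol_L),
                weight_g=float(row.weight_g),
                baseline_latency_s=trimmed_baseline(reps),
            )
        )
    return records


def read_measurements_csv(path) -> pd.DataFrame:
    """Read a long-format measurement table (mouse_id, t_min, latency_s)."""
    df = pd.read_csv(path)
    missing = [c for c in _MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"measurement CSV missing columns: {missing}")
    if df.empty:
        raise SchemaError("measurement CSV contains no rows")
    if (df["t_min"] < 0).any() or (df["latency_s"] < 0).any():
        raise SchemaError("t_min and latency_s must be non-negative")
    return df[_MEASUREMENT_COLUMNS].copy()
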