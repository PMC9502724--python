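"""End-to-end analysis pipeline: exclusions -> %MPE -> kinetics -> discrimination.

The pipeline is a pure function of (input tables, config): repeated runs
produce byte-identical reports.  Floats are serialized at six significant
digits with round-half-even so reports are diffable, and p-values carry the
study's two significance tiers as labels (significant at p < 0.05, notably
significant at p < 0.1) rather than truncated numbers.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import assay, kinetics, stats
from .assay import AssayConfig, MouseRecord, MPEValue, PLANTAR, SchemaError
from .design import DesignSpec
from .kinetics import BlockDuration, CubicFit, IntervalSummary, NoBlockError
from .simulate import CONDITIONS, TREATMENTS

__all__ = [
    "PipelineConfig",
    "StudyReport",
    "PipelineError",
    "run_pipeline",
    "write_report",
    "recover_duration",
]

log = logging.getLogger("nerveblock")

_FIT_MODES = ("cubic", "piecewise", "multi-segment")
_ROC_AGGREGATIONS = ("measurement", "window-mean", "mouse-mean")


class PipelineError(ValueError):
    """A structured pipeline failure naming the offending arm or input."""

    def __init__(self, message: str, arm: str | None = None):
        super().__init__(message if arm is None else f"[arm {arm}] {message}")
        self.arm = arm


@dataclass(frozen=True)
class PipelineConfig:
    assay: AssayConfig = PLANTAR
    design: DesignSpec = field(default_factory=lambda: DesignSpec(n_mice_per_group=6))
    mpe_threshold_pct: float = kinetics.DIMINISHED_MPE_PCT
    fit_mode: str = "piecewise"  # cubic | piecewise | multi-segment
    segments: tuple[tuple[float, float], ...] = ()  # sub-domains for multi-segment fits
    roc_aggregation: str = "window-mean"  # measurement | window-mean | mouse-mean
    t_test_variant: str = "pooled"
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.mpe_threshold_pct < 100):
            raise ValueError("mpe_threshold_pct must lie in (0, 100)")
        if self.fit_mode not in _FIT_MODES:
            raise ValueError(f"fit_mode must be one of {_FIT_MODES}")
        if self.roc_aggregation not in _ROC_AGGREGATIONS:
            raise ValueError(f"roc_aggregation must be one of {_ROC_AGGREGATIONS}")
        if self.t_test_variant not in ("pooled", "welch"):
            raise ValueError("t_test_variant must be 'pooled' or 'welch'")
        if self.fit_mode == "multi-segment" and not self.segments:
            raise ValueError("multi-segment fit mode needs at least one (lo, hi) segment")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {}
        if "assay" in raw:
            a = raw["assay"]
            if isinstance(a, str):
                kwargs["assay"] = {"plantar": PLANTAR, "tail_flick": assay.TAIL_FLICK}[a]
            else:
                kwargs["assay"] = AssayConfig(**a)
        if "design" in raw:
            kwargs["design"] = DesignSpec(**raw["design"])
        for key in ("mpe_threshold_pct", "fit_mode", "roc_aggregation", "t_test_variant", "output_dir"):
            if key in raw:
                kwargs[key] = raw[key]
        if "segments" in raw:
            kwargs["segments"] = tuple(tuple(seg) for seg in raw["segments"])
        return cls(**kwargs)


@dataclass
class StudyReport:
    data: dict

    def to_json(self) -> str:
        return json.dumps(_round_floats(self.data), sort_keys=True, indent=2, allow_nan=False)


# ---------------------------------------------------------------------------
# serialization helpers

def _round_sig(x: float, sig: int = 6) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return float(np.format_float_positional(x, precision=sig, unique=False, fractional=False))


def _round_floats(obj):
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        if math.isnan(x):
            return None
        if math.isinf(x):
            return "inf" if x > 0 else "-inf"
        return _round_sig(x)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _significance(p: float) -> str:
    if p < 0.05:
        return "significant (p < 0.05)"
    if p < 0.1:
        return "notably significant (p < 0.1)"
    return "not significant"


def _duration_dict(d: BlockDuration | None, error: str | None = None) -> dict:
    if error is not None:
        return {"status": "error", "message": error}
    assert d is not None
    return {
        "status": "censored_above_total" if d.censored_above_total else "estimated",
        "duration_min": d.duration_min,
        "threshold_pct": d.threshold_pct,
        "method": d.method,
    }


def _fit_dict(fit: CubicFit) -> dict:
    return {
        "coefficients": list(fit.coefficients),
        "domain": list(fit.domain),
        "r_squared": fit.r_squared,
    }


# ---------------------------------------------------------------------------
# stages

def _arm_key(condition: str, treatment: str) -> str:
    return f"{condition}:{treatment}"


def _mpe_for_arm(
    arm_mice: Sequence[MouseRecord], measurements: pd.DataFrame, cutoff: float
) -> list[MPEValue]:
    by_id = {m.mouse_id: m for m in arm_mice}
    sub = measurements[measurements["mouse_id"].isin(by_id)]
    values = []
    for row in sub.itertuples(index=False):
        pre = by_id[str(row.mouse_id)].baseline_latency_s
        post = min(float(row.latency_s), cutoff)
        values.append(
            MPEValue(
                mouse_id=str(row.mouse_id),
                t_min=float(row.t_min),
                mpe_pct=assay.compute_mpe(pre, post, cutoff),
            )
        )
    return values


def _roc_scores(
    mpe_by_arm: Mapping[str, list[MPEValue]],
    summaries_by_arm: Mapping[str, list[IntervalSummary]],
    arm: str,
    aggregation: str,
) -> list[float]:
    if aggregation == "measurement":
        return [v.mpe_pct for v in mpe_by_arm[arm]]
    if aggregation == "window-mean":
        return [s.mean_mpe_pct for s in summaries_by_arm[arm] if s.n >= 1]
    # mouse-mean
    acc: dict[str, list[float]] = {}
    for v in mpe_by_arm[arm]:
        acc.setdefault(v.mouse_id, []).append(v.mpe_pct)
    return [float(np.mean(vs)) for _, vs in sorted(acc.items())]


def _t_test_dict(res: stats.TTestResult) -> dict:
    return {
        "t": res.t,
        "df": res.df,
        "p_value": res.p_value,
        "group_means": list(res.group_means),
        "group_sds": list(res.group_sds),
        "group_ns": list(res.group_ns),
        "variant": res.variant,
        "significance": _significance(res.p_value),
    }


def run_pipeline(cohort_csv, measurements_csv, config: PipelineConfig | None = None) -> StudyReport:
    """Run the full analysis over a cohort table and a measurement table.

    Stages: sensory exclusions -> per-measurement %MPE -> per-window group
    summaries -> cubic fit, landmarks, and block duration per arm -> ROC
    discrimination models with AUC contrasts -> t-tests on cohort covariates.
    Every exclusion and every design parameter in effect is logged.
    """
    config = config or PipelineConfig()
    cutoff = config.assay.cutoff_s
    log.info("pipeline config: %s", config)

    cohort = assay.read_cohort_csv(cohort_csv)
    measurements = assay.read_measurements_csv(measurements_csv)

    included, excluded = assay.apply_sensory_exclusions(cohort, config.assay)
    for rec in excluded:
        log.info("excluded %s: %s", rec.mouse_id, rec.exclusion_reason)

    arms: dict[str, list[MouseRecord]] = {
        _arm_key(c, t): [m for m in included if m.condition == c and m.treatment == t]
        for c in CONDITIONS
        for t in TREATMENTS
    }

    mpe_by_arm: dict[str, list[MPEValue]] = {}
    summaries_by_arm: dict[str, list[IntervalSummary]] = {}
    arm_reports: dict[str, dict] = {}
    for arm, arm_mice in arms.items():
        if not arm_mice:
            raise PipelineError("no included mice", arm=arm)
        mpe = _mpe_for_arm(arm_mice, measurements, cutoff)
        if not mpe:
            raise PipelineError("no measurements for included mice", arm=arm)
        mpe_by_arm[arm] = mpe
        summaries = kinetics.summarize_intervals(mpe, config.design)
        summaries_by_arm[arm] = summaries

        report: dict[str, Any] = {
            "n_mice": len(arm_mice),
            "n_measurements": len(mpe),
            "interval_summaries": [asdict(s) for s in summaries],
        }
        try:
            fit = kinetics.fit_cubic(summaries)
            report["cubic_fit"] = _fit_dict(fit)
            report["landmarks"] = [asdict(l) for l in kinetics.extract_landmarks(fit)]
        except ValueError as err:
            raise PipelineError(str(err), arm=arm) from err

        try:
            d_fit = kinetics.block_duration(fit, config.mpe_threshold_pct, config.design.total_min)
            report["duration_fit"] = _duration_dict(d_fit)
        except NoBlockError as err:
            d_fit = None
            report["duration_fit"] = _duration_dict(None, error=str(err))
        try:
            d_means = kinetics.block_duration(
                summaries, config.mpe_threshold_pct, config.design.total_min
            )
            report["duration_means"] = _duration_dict(d_means)
        except NoBlockError as err:
            d_means = None
            report["duration_means"] = _duration_dict(None, error=str(err))

        if config.fit_mode == "multi-segment":
            seg_fits = []
            for lo, hi in config.segments:
                try:
                    seg_fit = kinetics.fit_cubic(summaries, domain=(lo, hi))
                    seg_fits.append(_fit_dict(seg_fit))
                except ValueError as err:
                    seg_fits.append({"domain": [lo, hi], "error": str(err)})
            report["segment_fits"] = seg_fits

        headline = report["duration_fit"] if config.fit_mode == "cubic" else report["duration_means"]
        report["duration"] = dict(headline)
        arm_reports[arm] = report

    # ROC models: "LA" pair discriminates condition within a fixed anesthetic,
    # "condition" pair discriminates anesthetic within a fixed condition.
    def _model(arm_a: str, arm_b: str, labels: tuple[str, str], positive: str):
        scores = [
            (s, labels[0]) for s in _roc_scores(mpe_by_arm, summaries_by_arm, arm_a, config.roc_aggregation)
        ] + [
            (s, labels[1]) for s in _roc_scores(mpe_by_arm, summaries_by_arm, arm_b, config.roc_aggregation)
        ]
        return stats.roc_from_scores(scores, positive_label=positive)

    roc_models = {
        "LA:BH": _model("control:BH", "dm_pn:BH", ("control", "dm_pn"), "dm_pn"),
        "LA:LB": _model("control:LB", "dm_pn:LB", ("control", "dm_pn"), "dm_pn"),
        "condition:control": _model("control:BH", "control:LB", ("BH", "LB"), "LB"),
        "condition:dm_pn": _model("dm_pn:BH", "dm_pn:LB", ("BH", "LB"), "LB"),
    }
    comparisons = {
        "LA": stats.compare_auc(roc_models["LA:BH"], roc_models["LA:LB"]),
        "condition": stats.compare_auc(
            roc_models["condition:control"], roc_models["condition:dm_pn"]
        ),
    }

    # covariate t-tests between conditions on the full (pre-exclusion) cohort
    def _cov(attr):
        a = [getattr(m, attr) for m in cohort if m.condition == "dm_pn"]
        b = [getattr(m, attr) for m in cohort if m.condition == "control"]
        return stats.t_test_from_raw(a, b, variant=config.t_test_variant)

    covariates = {
        name: _t_test_dict(_cov(attr))
        for name, attr in [
            ("glucose_mmol_L", "fasting_glucose_mmol_L"),
            ("weight_g", "weight_g"),
            ("baseline_latency_s", "baseline_latency_s"),
        ]
    }

    data = {
        "provenance": {
            "config": {
                "assay": asdict(config.assay),
                "design": asdict(config.design),
                "mpe_threshold_pct": config.mpe_threshold_pct,
                "fit_mode": config.fit_mode,
                "roc_aggregation": config.roc_aggregation,
                "t_test_variant": config.t_test_variant,
            },
            "n_cohort": len(cohort),
            "n_included": len(included),
            "n_measurements_total": int(len(measurements)),
        },
        "exclusions": [
            {"mouse_id": r.mouse_id, "condition": r.condition, "treatment": r.treatment,
             "reason": r.exclusion_reason}
            for r in excluded
        ],
        "arms": arm_reports,
        "roc_models": {
            name: {
                "auc": r.auc,
                "se": r.se,
                "n_pos": r.n_pos,
                "n_neg": r.n_neg,
                "positive_label": r.positive_label,
                "points": [list(p) for p in r.points],
            }
            for name, r in roc_models.items()
        },
        "auc_comparisons": {
            name: {
                "auc_1": c.auc_1,
                "auc_2": c.auc_2,
                "chi2": c.chi2,
                "df": c.df,
                "p_value": c.p_value,
                "significance": _significance(c.p_value),
            }
            for name, c in comparisons.items()
        },
        "covariate_t_tests": covariates,
    }
    return StudyReport(data=data)


def recover_duration(profile, seed: int, n_mice: int = 6) -> BlockDuration:
    """Simulate one arm under a known block profile and estimate its duration.

    Calibration utility: runs the full chain (cohort draw, sensory
    exclusions, interleaved schedule, censored trajectories, %MPE, interval
    means, duration estimate) for a single control arm, so the estimate can
    be compared against the profile's true ``duration_min``.
    """
    from . import simulate
    from .design import generate_schedule

    spec = simulate.CohortSpec(n_per_arm=n_mice, seed=seed, baseline_rep_sd_s=0.0)
    rng = np.random.default_rng(seed)
    mice = [
        m
        for m in simulate.generate_cohort(spec, rng)
        if m.condition == "control" and m.treatment == "BH"
    ]
    included, _ = assay.apply_sensory_exclusions(mice, PLANTAR)
    design = DesignSpec(n_mice_per_group=len(included), seed=seed)
    schedule = generate_schedule(design, [m.mouse_id for m in included])
    times: dict[str, list[float]] = {}
    for e in schedule:
        times.setdefault(e.mouse_id, []).append(e.slot_time_min)
    cutoff = spec.cutoff_s
    mpe = []
    for m in included:
        for meas in simulate.generate_trajectory(m, profile, sorted(times[m.mouse_id]), cutoff, rng):
            mpe.append(
                MPEValue(m.mouse_id, meas.t_min, assay.compute_mpe(m.baseline_latency_s, meas.latency_s, cutoff))
            )
    return kinetics.block_duration(kinetics.summarize_intervals(mpe, design))


# ---------------------------------------------------------------------------
# outputs

def write_report(report: StudyReport, output_dir, figures: bool = True) -> Path:
    """Write report.json, tidy CSV side-tables, and per-arm trajectory figures."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json() + "\n", encoding="utf-8")

    rows = []
    for arm, rep in report.data["arms"].items():
        for s in rep["interval_summaries"]:
            rows.append({"arm": arm, **s})
    pd.DataFrame(rows).to_csv(out / "interval_summaries.csv", index=False)

    roc_rows = []
    for model, rep in report.data["roc_models"].items():
        for fpr, tpr in rep["points"]:
            roc_rows.append({"model": model, "fpr": fpr, "tpr": tpr})
    pd.DataFrame(roc_rows).to_csv(out / "roc_points.csv", index=False)

    if figures:
        _write_figures(report, out / "figures")
    return out / "report.json"


def _write_figures(report: StudyReport, fig_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir.mkdir(parents=True, exist_ok=True)
    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5), sharey=True)
    by_treatment: dict[str, list[str]] = {"BH": [], "LB": []}
    for arm in report.data["arms"]:
        by_treatment[arm.split(":")[1]].append(arm)
    for ax, (treatment, arms) in zip(axes, sorted(by_treatment.items())):
        for arm in sorted(arms):
            rep = report.data["arms"][arm]
            mids = [s["midpoint_min"] for s in rep["interval_summaries"] if s["n"] >= 1]
            means = [s["mean_mpe_pct"] for s in rep["interval_summaries"] if s["n"] >= 1]
            sds = [
                0.0 if s["sd_mpe_pct"] is None or not math.isfinite(s["sd_mpe_pct"] or math.nan)
                else s["sd_mpe_pct"]
                for s in rep["interval_summaries"]
                if s["n"] >= 1
            ]
            ax.errorbar(mids, means, yerr=sds, fmt="o", ms=3, capsize=2, label=arm, alpha=0.8)
            if "cubic_fit" in rep:
                lo, hi = rep["cubic_fit"]["domain"]
                tt = np.linspace(lo, hi, 300)
                coeffs = rep["cubic_fit"]["coefficients"]
                ax.plot(tt, np.polynomial.polynomial.polyval(tt, coeffs), lw=1)
        ax.axhline(15, color="grey", ls="--", lw=0.8)
        ax.set_title(treatment)
        ax.set_xlabel("time since injection (min)")
        ax.legend(fontsize=8)
    axes[0].set_ylabel("mean %MPE")
    fig.tight_layout()
    fig.savefig(fig_dir / "block_trajectories.png", dpi=120)
    plt.close(fig)
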