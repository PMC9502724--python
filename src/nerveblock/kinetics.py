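"""Block kinetics: interval summaries, cubic fits, landmarks, duration.

Group-level block intensity is summarised as the mean %MPE per 13.5-min
window.  A third-order polynomial is fitted to the window means by ordinary
least squares and evaluated continuously; its global maximum marks block
onset and an interior local minimum a partial release.  The sensory block is
considered diminished once the %MPE trajectory falls below a threshold
(default 15%) and does not re-exceed it before the end of the analysis
horizon; if the trajectory is still above threshold at the horizon the
duration is censored.

Two duration paths are exposed: the fitted cubic (analytic root-finding on
the polynomial minus the threshold) and the interval means themselves
(piecewise-linear interpolation between window midpoints, refined by a local
regression around the crossing).  A single cubic over the whole horizon is a
coarse descriptive model — a rise-plateau-fall trajectory is not cubic — so
the means path is the quantitative default in the pipeline, and per-segment
cubic fits over user-chosen sub-domains are supported for trajectories with
several release marks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from numpy.polynomial import Polynomial

from .assay import MPEValue
from .design import DesignSpec

__all__ = [
    "IntervalSummary",
    "CubicFit",
    "Landmark",
    "BlockDuration",
    "NoBlockError",
    "summarize_intervals",
    "fit_cubic",
    "extract_landmarks",
    "block_duration",
]

#: group-mean %MPE below which the block counts as diminished
DIMINISHED_MPE_PCT = 15.0


class NoBlockError(ValueError):
    """The trajectory never reaches the diminished-block threshold."""


@dataclass(frozen=True)
class IntervalSummary:
    """Mean +/- SD of %MPE inside one half-open sampling window."""

    window_index: int
    midpoint_min: float
    mean_mpe_pct: float  # NaN when n == 0
    sd_mpe_pct: float  # sample SD; NaN when n < 2
    n: int


@dataclass(frozen=True)
class CubicFit:
    """OLS cubic of mean %MPE on time, with its valid domain and R^2."""

    coefficients: tuple[float, float, float, float]  # a0 + a1 t + a2 t^2 + a3 t^3
    domain: tuple[float, float]
    r_squared: float

    def __call__(self, t):
        return Polynomial(self.coefficients)(np.asarray(t, dtype=float))


@dataclass(frozen=True)
class Landmark:
    kind: str  # onset_peak | release_local_min | diminished_crossing
    t_min: float
    mpe_pct: float
    at_boundary: bool = False  # True when the landmark sits on a domain end


@dataclass(frozen=True)
class BlockDuration:
    """Estimated block duration from injection (t = 0), or censoring flag.

    ``duration_min`` is None when ``censored_above_total`` is True: the
    trajectory was still above threshold at the end of the analysis horizon.
    """

    duration_min: float | None
    censored_above_total: bool
    threshold_pct: float
    method: str  # "fit" | "interval_means"

    @property
    def label(self) -> str:
        if self.censored_above_total:
            return "censored_above_total"
        return f"{self.duration_min:.1f} min"


def summarize_intervals(
    mpe_values: Iterable[MPEValue], spec: DesignSpec
) -> list[IntervalSummary]:
    """One summary per window; values bin by the half-open convention.

    A value at exactly t = w * window_min belongs to window w.  Empty windows
    are reported with n = 0 and NaN mean so downstream fits can skip them
    without renumbering.
    """
    values = list(mpe_values)
    for v in values:
        if v.t_min >= spec.total_min:
            raise ValueError(f"t_min {v.t_min} outside the {spec.total_min}-min horizon")
        if v.t_min < 0:
            raise ValueError("t_min must be non-negative")
    out = []
    for w in range(spec.n_windows):
        lo = w * spec.window_min
        inside = np.array(
            [v.mpe_pct for v in values if lo <= v.t_min < lo + spec.window_min], dtype=float
        )
        n = inside.size
        mean = float(inside.mean()) if n else math.nan
        sd = float(inside.std(ddof=1)) if n >= 2 else math.nan
        out.append(
            IntervalSummary(
                window_index=w,
                midpoint_min=lo + spec.window_min / 2,
                mean_mpe_pct=mean,
                sd_mpe_pct=sd,
                n=int(n),
            )
        )
    return out


def _usable(summaries: Sequence[IntervalSummary]) -> tuple[np.ndarray, np.ndarray]:
    pts = [(s.midpoint_min, s.mean_mpe_pct) for s in summaries if s.n >= 1]
    pts = [(t, y) for t, y in pts if math.isfinite(y)]
    if not pts:
        return np.array([]), np.array([])
    t, y = map(np.asarray, zip(*pts))
    return t.astype(float), y.astype(float)


def fit_cubic(
    summaries: Sequence[IntervalSummary], domain: tuple[float, float] | None = None
) -> CubicFit:
    """Unweighted OLS cubic of the window means on window midpoints.

    Only windows with at least one observation enter the fit; restricting
    ``domain`` fits one segment of a multi-phase trajectory.  The solve is
    performed on centred/scaled time for conditioning and the coefficients
    are mapped back exactly by polynomial composition.  R^2 of a
    zero-variance response is defined as 0 (with a warning) so that
    0 <= R^2 <= 1 always holds.
    """
    t, y = _usable(summaries)
    if domain is not None:
        keep = (t >= domain[0]) & (t <= domain[1])
        t, y = t[keep], y[keep]
    if t.size < 4:
        raise ValueError("underdetermined cubic: need >= 4 windows with observations")
    c = t.mean()
    h = (t.max() - t.min()) / 2 or 1.0
    s = (t - c) / h
    coef_s, *_ = np.linalg.lstsq(np.vander(s, 4, increasing=True), y, rcond=None)
    poly = Polynomial(coef_s)(Polynomial([-c / h, 1.0 / h]))
    coeffs = np.zeros(4)
    coeffs[: len(poly.coef)] = poly.coef
    fitted = Polynomial(coeffs)(t)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
        r2 = float(min(1.0, max(0.0, r2)))
    else:
        warnings.warn("zero-variance response: R^2 reported as 0", stacklevel=2)
        r2 = 0.0
    dom = domain if domain is not None else (float(t.min()), float(t.max()))
    return CubicFit(coefficients=tuple(float(a) for a in coeffs), domain=dom, r_squared=r2)


def extract_landmarks(fit: CubicFit) -> list[Landmark]:
    """Onset and release landmarks of a fitted cubic over its closed domain.

    Stationary points come from the analytic roots of the derivative
    quadratic and are classified by the second derivative; global extrema
    include the domain endpoints.  The onset peak is the global maximum
    (earliest time on ties); an interior local minimum, when present, is the
    block-release landmark.
    """
    a0, a1, a2, a3 = fit.coefficients
    lo, hi = fit.domain
    p = Polynomial(fit.coefficients)
    candidates = [lo, hi]
    interior_min: tuple[float, float] | None = None
    if a3 != 0:
        disc = (2 * a2) ** 2 - 4 * (3 * a3) * a1
        if disc >= 0:
            for r in sorted(
                [(-2 * a2 - math.sqrt(disc)) / (6 * a3), (-2 * a2 + math.sqrt(disc)) / (6 * a3)]
            ):
                if lo < r < hi:
                    candidates.append(r)
                    second = 2 * a2 + 6 * a3 * r
                    if second > 0:
                        interior_min = (r, float(p(r)))
    elif a2 != 0:
        r = -a1 / (2 * a2)
        if lo < r < hi:
            candidates.append(r)
            if a2 > 0:
                interior_min = (r, float(p(r)))
    values = [(float(p(t)), t) for t in candidates]
    peak_val, peak_t = max(values, key=lambda vt: (vt[0], -vt[1]))
    landmarks = [
        Landmark(
            kind="onset_peak",
            t_min=float(peak_t),
            mpe_pct=peak_val,
            at_boundary=peak_t in (lo, hi),
        )
    ]
    if interior_min is not None:
        landmarks.append(
            Landmark(kind="release_local_min", t_min=interior_min[0], mpe_pct=interior_min[1])
        )
    return landmarks


def _duration_from_fit(fit: CubicFit, threshold: float) -> BlockDuration:
    lo, hi = fit.domain
    p = Polynomial(fit.coefficients)
    peak = extract_landmarks(fit)[0]
    if peak.mpe_pct < threshold:
        raise NoBlockError("no block established: fitted peak below threshold")
    if peak.mpe_pct == threshold:  # a tie at the threshold already counts as diminished
        return BlockDuration(float(peak.t_min), False, threshold, "fit")
    if float(p(hi)) >= threshold:
        return BlockDuration(None, True, threshold, "fit")
    q = p - threshold
    roots = q.roots()
    real = sorted(
        float(r.real)
        for r in roots
        if abs(r.imag) < 1e-9 and peak.t_min < r.real <= hi + 1e-9
    )
    # after the last real crossing the curve keeps the (sub-threshold) sign it
    # has at the domain end, so that crossing is the diminished time
    if not real:
        raise NoBlockError("no downward crossing located inside the fit domain")
    return BlockDuration(float(min(real[-1], hi)), False, threshold, "fit")


def _scan_diminished(y: np.ndarray, threshold: float, run: int = 2) -> tuple[int | None, int]:
    """Locate the sustained fall below threshold after the peak.

    Scanning forward from the global peak, the block counts as diminished at
    the first window below threshold that is confirmed by the next window (or
    by the end of the horizon); a re-exceedance only counts as a genuine
    re-block when it is likewise sustained over ``run`` consecutive windows,
    so a single noisy window cannot flip the call either way.  Returns
    (diminished index or None if censored, index the final decay starts from).
    """
    n = y.size
    anchor = int(np.argmax(y))
    start = anchor
    while True:
        below = None
        for j in range(start + 1, n):
            if y[j] < threshold and (j + run > n or bool(np.all(y[j : j + run] < threshold))):
                below = j
                break
        if below is None:
            return None, anchor  # still above threshold at the end of the horizon
        reblock = None
        for j in range(below + 1, n):
            if y[j] >= threshold and (j + run > n or bool(np.all(y[j : j + run] >= threshold))):
                reblock = j
                break
        if reblock is None:
            return below, anchor
        start = anchor = reblock


def _logistic_crossing(
    t: np.ndarray,
    y: np.ndarray,
    se: np.ndarray,
    anchor: int,
    kb: int,
    threshold: float,
    fallback: float,
) -> float:
    """Refine the crossing with a logistic decay fitted from the anchor on.

    A three-parameter logistic A / (1 + exp((t - m)/s)) pools every window of
    the terminal decay, which averages measurement noise far better than the
    two bracketing means alone.  Window means are heteroscedastic — an animal
    whose baseline sits near the cutoff contributes a tiny %MPE denominator
    and hence very noisy scores — so the fit is weighted by each window's own
    standard error (floored at one %MPE point).  The analytic threshold
    crossing of the fitted curve is clamped to within one window of the
    observed bracket; plain interpolation is the fallback when the fit fails.
    """
    from scipy.optimize import curve_fit

    tt, yy, ss = t[anchor:], y[anchor:], np.maximum(se[anchor:], 1.0)
    if tt.size < 4:
        return fallback
    width = float(np.median(np.diff(t))) if t.size > 1 else 13.5

    def f(x, a, m, s):
        return a / (1.0 + np.exp((x - m) / s))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            (a, m, s), _ = curve_fit(
                f,
                tt,
                yy,
                p0=[max(float(yy[0]), threshold + 1.0), fallback, 15.0],
                sigma=ss,
                bounds=([1.0, float(tt[0]), 1.0], [110.0, float(tt[-1]) + 200.0, 120.0]),
                maxfev=5000,
            )
    except (RuntimeError, ValueError):
        return fallback
    if a <= threshold:
        return fallback
    crossing = m + s * math.log(a / threshold - 1.0)
    lo = t[kb - 1] - width if kb >= 1 else t[0]
    hi = t[kb] + width
    return float(min(max(crossing, lo), hi))


def _duration_from_means(
    summaries: Sequence[IntervalSummary], threshold: float, total_min: float
) -> BlockDuration:
    usable = [
        s for s in summaries if s.n >= 1 and math.isfinite(s.mean_mpe_pct)
    ]
    if len(usable) < 2:
        raise ValueError("need at least two populated windows")
    t = np.array([s.midpoint_min for s in usable])
    y = np.array([s.mean_mpe_pct for s in usable])
    se = np.array(
        [
            s.sd_mpe_pct / math.sqrt(s.n) if math.isfinite(s.sd_mpe_pct) else 1.0
            for s in usable
        ]
    )
    if float(y.max()) < threshold:
        raise NoBlockError("no block established: no window mean reaches the threshold")
    kb, anchor = _scan_diminished(y, threshold)
    if kb is None:
        return BlockDuration(None, True, threshold, "interval_means")
    # last above-threshold window before the confirmed diminished one
    k = kb - 1
    while k > 0 and y[k] < threshold:
        k -= 1
    if y[k] < threshold:
        crossing = float(t[kb])
    else:
        t0, t1, y0, y1 = t[k], t[kb], y[k], y[kb]
        interp = float(t0 + (y0 - threshold) / (y0 - y1) * (t1 - t0))
        crossing = _logistic_crossing(t, y, se, anchor, kb, threshold, interp)
    return BlockDuration(crossing, False, threshold, "interval_means")


def block_duration(
    source: CubicFit | Sequence[IntervalSummary],
    threshold_pct: float = DIMINISHED_MPE_PCT,
    total_min: float = 270.0,
) -> BlockDuration:
    """Block duration from injection until the trajectory stays below threshold.

    Accepts either a fitted cubic (crossing located by analytic root-finding
    on the polynomial minus the threshold) or the interval summaries
    themselves (piecewise-linear crossing between window midpoints).  Returns
    a censored result when the trajectory has not settled below threshold by
    the end of the domain/horizon; raises :class:`NoBlockError` when it never
    reaches the threshold at all.
    """
    if isinstance(source, CubicFit):
        return _duration_from_fit(source, threshold_pct)
    return _duration_from_means(source, threshold_pct, total_min)
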