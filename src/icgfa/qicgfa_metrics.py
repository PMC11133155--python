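"""Conventional quantitative ICGFA descriptors.

Implements the descriptor set commonly reported for fluorescence
time-intensity curves: latency (pre-inflow period), Fmax, Tmax, T1/2,
in/outflow slopes, intensity and gradient at 50 and 100 s post peak, the
TR ratio (T1/2 : Tmax) and the intensity-weighted centre of mass.

Onset detection uses a sustained-threshold rule (default: the curve
reaches 0.10 and stays there for at least 1 s). For metric computation the
detected crossing is back-projected along the local inflow slope to the
inflow foot, so that latency measures the true pre-inflow period; on a
linear inflow this makes TR exactly 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .curve_match import CurveFitResult
from .errors import UnquantifiableCurveError
from .signal_io import PerfusionCurve

#: column order mirrors the conventional per-ROI descriptor tables
METRIC_COLUMNS = [
    "latency_s", "upslope", "t_half_s", "fmax", "tmax_s", "downslope",
    "t50_s", "f50", "d50", "t100_s", "f100", "d100", "tr", "centre_of_mass_s",
]


@dataclass
class QICGFAMetrics:
    latency_s: float
    fmax: float
    tmax_s: float
    t_half_s: float
    upslope: float
    downslope: float
    t50_s: float
    f50: float
    d50: float
    t100_s: float
    f100: float
    d100: float
    tr: float
    centre_of_mass_s: float
    flags: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in METRIC_COLUMNS}
        d["flags"] = ";".join(self.flags)
        return d


def _crossing_time(t: np.ndarray, y: np.ndarray, i: int, level: float) -> float:
    """Linear-interpolated upward crossing of ``level`` ending at sample i."""
    if i == 0 or y[i - 1] >= level:
        return float(t[i])
    frac = (level - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def detect_onset(
    curve: PerfusionCurve,
    threshold: float = 0.10,
    sustain_s: float = 1.0,
    extrapolate: bool = False,
) -> float:
    """Time of inflow onset on a normalized curve.

    Finds the first time the curve reaches ``threshold`` and stays at or
    above it for at least ``sustain_s``. With ``extrapolate=True`` the
    crossing is projected back along the local inflow slope to the inflow
    foot (intensity 0), clipped to the recording start.
    """
    t = curve.times_s
    y = curve.intensities
    above = y >= threshold
    if not above.any():
        raise UnquantifiableCurveError("no inflow detected")
    # runs of consecutive above-threshold samples
    edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
    starts, ends = edges[::2], edges[1::2]  # [start, end)
    for i0, i1 in zip(starts, ends):
        if t[i1 - 1] - t[i0] >= sustain_s:
            t_cross = _crossing_time(t, y, i0, threshold)
            if not extrapolate:
                return t_cross
            win = (t >= t_cross) & (t <= t_cross + sustain_s)
            tw, yw = t[win], y[win]
            if tw.size >= 2:
                slope = np.polyfit(tw, yw, 1)[0]
                if slope > 0:
                    return float(np.clip(t_cross - threshold / slope, t[0], t_cross))
            return t_cross
    raise UnquantifiableCurveError("no inflow detected")


def _ls_slope(t: np.ndarray, y: np.ndarray) -> float:
    if t.size < 2 or np.ptp(t) == 0:
        return np.nan
    return float(np.polyfit(t, y, 1)[0])


def compute_metrics(
    curve: PerfusionCurve,
    onset_threshold: float = 0.10,
    onset_sustain_s: float = 1.0,
    slope_halfwindow_s: float = 5.0,
) -> QICGFAMetrics:
    """Full descriptor set for one normalized determinative curve."""
    t = curve.times_s
    y = curve.intensities
    flags: List[str] = []
    onset = detect_onset(curve, onset_threshold, onset_sustain_s, extrapolate=True)
    i_peak = int(np.argmax(y))
    t_peak = float(t[i_peak])
    fmax = float(y[i_peak])
    if t_peak <= onset:
        raise UnquantifiableCurveError("peak not after inflow onset")
    tmax_s = t_peak - onset

    # first upward crossing of fmax/2 at or after onset
    half = fmax / 2.0
    after = np.flatnonzero((t >= onset) & (y >= half))
    i_half = int(after[0])
    t_half_s = _crossing_time(t, y, i_half, half) - onset
    tr = t_half_s / tmax_s

    rise = (t >= onset) & (t <= t_peak)
    upslope = _ls_slope(t[rise], y[rise])
    fall = t >= t_peak
    if fall.sum() < 2:
        downslope = np.nan
        flags.append("downslope_undefined")
    else:
        downslope = _ls_slope(t[fall], y[fall])

    def post_peak(offset: float):
        tp = t_peak + offset
        if tp > t[-1]:
            flags.append(f"t{int(offset)}_beyond_recording")
            return np.nan, np.nan, np.nan
        f = float(np.interp(tp, t, y))
        win = (t >= tp - slope_halfwindow_s) & (t <= tp + slope_halfwindow_s)
        return tp, f, _ls_slope(t[win], y[win])

    t50_s, f50, d50 = post_peak(50.0)
    t100_s, f100, d100 = post_peak(100.0)

    total = float(y.sum())
    com = float((t * y).sum() / total) if total > 0 else np.nan

    return QICGFAMetrics(
        latency_s=onset, fmax=fmax, tmax_s=tmax_s, t_half_s=t_half_s,
        upslope=upslope, downslope=downslope,
        t50_s=t50_s, f50=f50, d50=d50, t100_s=t100_s, f100=f100, d100=d100,
        tr=tr, centre_of_mass_s=com, flags=flags,
    )


def metrics_table(
    curves: Sequence[PerfusionCurve],
    fits: Optional[Sequence[CurveFitResult]] = None,
) -> pd.DataFrame:
    """One row per ROI: descriptors plus (optionally) the curve-fit outputs.

    Curves whose descriptors cannot be computed keep their row with NaN
    metrics and a flag — no silent drops. Missing values are NaN.
    """
    if not curves:
        raise ValueError("need at least one curve")
    fit_by_pos = {f.position_index: f for f in fits} if fits else {}
    rows = []
    for c in curves:
        row: dict = {"roi_id": c.roi_id, "position_index": c.position_index}
        try:
            row.update(compute_metrics(c).to_dict())
        except UnquantifiableCurveError as exc:
            row.update({k: np.nan for k in METRIC_COLUMNS})
            row["flags"] = str(exc)
        fit = fit_by_pos.get(c.position_index)
        if fit is not None:
            row.update(
                scale_s=fit.scale_s, shift_tau_s=fit.shift_tau_s,
                fit_peak=fit.agreement, diff_curve_area=fit.diff_curve_area,
                fit_accepted=float(fit.accepted),
            )
        rows.append(row)
    return pd.DataFrame(rows)
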