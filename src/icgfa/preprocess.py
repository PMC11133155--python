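"""Curve conditioning: background removal, resampling, smoothing, normalization.

The fixed pipeline order is background subtraction -> resampling onto a
uniform grid -> Savitzky-Golay smoothing -> min-max normalization; the
order is recorded in each output curve's ``meta['pipeline']``. The whole
pipeline is invariant to positive affine transforms of the raw intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import ConfigError, UnquantifiableCurveError
from .signal_io import PerfusionCurve


@dataclass
class PreprocessConfig:
    baseline_window_s: float = 5.0
    sg_window_s: float = 1.0
    sg_polyorder: int = 3
    resample_hz: float = 10.0

    def __post_init__(self) -> None:
        if self.baseline_window_s < 0:
            raise ConfigError("baseline_window_s must be >= 0")
        if self.resample_hz <= 0:
            raise ConfigError("resample_hz must be > 0")
        if self.sg_window_samples <= self.sg_polyorder:
            raise ConfigError(
                "Savitzky-Golay window must exceed the polynomial order"
            )

    @property
    def sg_window_samples(self) -> int:
        """Odd window length in samples on the resampled grid."""
        n = max(int(round(self.sg_window_s * self.resample_hz)), 1)
        return n if n % 2 == 1 else n + 1

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


def subtract_background(curve: PerfusionCurve, cfg: PreprocessConfig) -> PerfusionCurve:
    """Remove the pre-injection background level.

    Subtracts the median intensity over the initial baseline window and
    floors the result at 0.
    """
    if cfg.baseline_window_s == 0:
        out = curve.replace(intensities=np.maximum(curve.intensities, 0.0))
    else:
        if curve.duration_s < cfg.baseline_window_s:
            raise ValueError("baseline window longer than the recorded curve")
        window = curve.times_s <= curve.times_s[0] + cfg.baseline_window_s
        level = float(np.median(curve.intensities[window]))
        out = curve.replace(intensities=np.maximum(curve.intensities - level, 0.0))
    out.meta.setdefault("pipeline", []).append("subtract_background")
    return out


def resample(curve: PerfusionCurve, cfg: PreprocessConfig) -> PerfusionCurve:
    """Linear interpolation onto a uniform grid at ``resample_hz`` over [0, duration]."""
    if curve.times_s.size < 2:
        raise ValueError("need at least 2 samples to resample")
    t0 = curve.times_s[0]
    duration = curve.duration_s
    n = int(round(duration * cfg.resample_hz)) + 1
    new_t = t0 + np.arange(n) / cfg.resample_hz
    new_i = np.interp(new_t, curve.times_s, curve.intensities)
    out = curve.replace(times_s=new_t, intensities=new_i)
    out.meta.setdefault("pipeline", []).append("resample")
    return out


def smooth(curve: PerfusionCurve, cfg: PreprocessConfig) -> PerfusionCurve:
    """Savitzky-Golay smoothing; requires a uniform grid."""
    if not curve.is_uniform():
        raise ValueError("smooth requires a uniformly resampled curve")
    window = cfg.sg_window_samples
    if window > curve.intensities.size:
        raise ValueError("Savitzky-Golay window exceeds curve length")
    out = curve.replace(
        intensities=savgol_filter(curve.intensities, window, cfg.sg_polyorder)
    )
    out.meta.setdefault("pipeline", []).append("smooth")
    return out


def normalize(curve: PerfusionCurve) -> PerfusionCurve:
    """Affine map of intensities onto [0, 1] (min -> 0, max -> 1)."""
    lo = float(curve.intensities.min())
    hi = float(curve.intensities.max())
    if hi <= lo:
        raise UnquantifiableCurveError(
            f"unquantifiable ROI {curve.roi_id}: constant intensity"
        )
    out = curve.replace(intensities=(curve.intensities - lo) / (hi - lo))
    out.meta.setdefault("pipeline", []).append("normalize")
    return out


def preprocess_curve(curve: PerfusionCurve, cfg: PreprocessConfig) -> PerfusionCurve:
    """Full conditioning pipeline in the fixed recorded order."""
    out = subtract_background(curve, cfg)
    out = resample(out, cfg)
    out = smooth(out, cfg)
    out = normalize(out)
    return out
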