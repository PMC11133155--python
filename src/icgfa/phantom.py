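"""Synthetic bowel-perfusion phantom with known ground truth.

Gamma-variate inflow with exponential washout onto a residual plateau is
used as the generative curve family. Ischemia is modeled as a joint
proximal-to-distal time dilation plus amplitude attenuation starting at a
configurable boundary position: time dilation carries the recoverable
signal (amplitude alone is removed by normalization).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Set, Tuple

import numpy as np

from .signal_io import PerfusionCurve, VideoStack


@dataclass
class KineticParams:
    """Parameters of one position's generative curve."""

    onset_t0_s: float = 15.0
    peak_tp_s: float = 45.0
    alpha: float = 2.5
    amplitude: float = 1.0
    washout_tau_s: float = 90.0
    plateau: float = 0.35

    def __post_init__(self) -> None:
        if self.peak_tp_s <= self.onset_t0_s:
            raise ValueError("peak_tp_s must exceed onset_t0_s")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not (0 <= self.plateau < 1):
            raise ValueError("plateau must lie in [0, 1)")
        if self.washout_tau_s <= 0:
            raise ValueError("washout_tau_s must be > 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")

    def dilated(self, time_factor: float, amp_factor: float = 1.0) -> "KineticParams":
        """Dilate the curve about its onset and attenuate its amplitude."""
        return replace(
            self,
            peak_tp_s=self.onset_t0_s + (self.peak_tp_s - self.onset_t0_s) * time_factor,
            washout_tau_s=self.washout_tau_s * time_factor,
            amplitude=self.amplitude * amp_factor,
        )


@dataclass
class PhantomSpec:
    n_rois: int = 11
    spacing_cm: float = 2.0
    ischemia_start_index: int = 6
    dilation_gradient: float = 1.3
    attenuation_gradient: float = 0.85
    noise_sigma: float = 0.02
    duration_s: float = 240.0
    rate_hz: float = 30.0
    seed: int = 0
    baseline: KineticParams = field(default_factory=KineticParams)

    def __post_init__(self) -> None:
        if not (0 <= self.ischemia_start_index <= self.n_rois):
            raise ValueError("ischemia_start_index must lie in [0, n_rois]")
        if self.dilation_gradient < 1:
            raise ValueError("dilation_gradient must be >= 1")
        if not (0 < self.attenuation_gradient <= 1):
            raise ValueError("attenuation_gradient must lie in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def times(self) -> np.ndarray:
        return np.arange(int(round(self.duration_s * self.rate_hz))) / self.rate_hz

    def position_params(self, i: int) -> KineticParams:
        power = max(0, i - self.ischemia_start_index + 1)
        return self.baseline.dilated(
            self.dilation_gradient ** power, self.attenuation_gradient ** power
        )

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "baseline" in d and isinstance(d["baseline"], dict):
            d["baseline"] = KineticParams(**d["baseline"])
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class PhantomGroundTruth:
    params: List[KineticParams]
    true_sufficient_set: Set[int]
    true_boundary_index: int

    def to_dict(self) -> dict:
        return {
            "true_boundary_index": self.true_boundary_index,
            "true_sufficient_set": sorted(self.true_sufficient_set),
            "params": [vars(p) for p in self.params],
        }


def gamma_variate_values(params: KineticParams, times: np.ndarray) -> np.ndarray:
    """Noise-free curve values: gamma-variate rise, exponential washout."""
    t = np.asarray(times, dtype=float)
    y = np.zeros_like(t)
    rise_span = params.peak_tp_s - params.onset_t0_s
    u = (t - params.onset_t0_s) / rise_span
    rising = (t >= params.onset_t0_s) & (t <= params.peak_tp_s)
    y[rising] = params.amplitude * u[rising] ** params.alpha * np.exp(
        params.alpha * (1.0 - u[rising])
    )
    falling = t > params.peak_tp_s
    y[falling] = params.amplitude * (
        (1.0 - params.plateau) * np.exp(-(t[falling] - params.peak_tp_s) / params.washout_tau_s)
        + params.plateau
    )
    return y


def gamma_variate(params: KineticParams, times: np.ndarray, **curve_kwargs) -> PerfusionCurve:
    return PerfusionCurve(
        times_s=np.asarray(times, dtype=float),
        intensities=gamma_variate_values(params, times),
        **curve_kwargs,
    )


def _noisy(y: np.ndarray, sigma: float, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, size=y.shape)
    # keep curves physical: nonnegative, bounded by amplitude + 5 sigma
    return np.clip(y, 0.0, amplitude + 5.0 * sigma)


def make_phantom(
    spec: PhantomSpec,
) -> Tuple[PerfusionCurve, List[PerfusionCurve], PhantomGroundTruth]:
    """Reference curve, per-position determinative curves, and ground truth.

    Positions at and beyond ``ischemia_start_index`` get compounding time
    dilation and amplitude attenuation. Fully deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    t = spec.times()
    ref_clean = gamma_variate_values(spec.baseline, t)
    ref = PerfusionCurve(
        times_s=t,
        intensities=_noisy(ref_clean, spec.noise_sigma, spec.baseline.amplitude, rng),
        roi_id="reference",
        position_index=0,
        source="reference",
    )
    params = [spec.position_params(i) for i in range(spec.n_rois)]
    dets = []
    for i, p in enumerate(params):
        clean = gamma_variate_values(p, t)
        dets.append(
            PerfusionCurve(
                times_s=t,
                intensities=_noisy(clean, spec.noise_sigma, p.amplitude, rng),
                roi_id=f"roi{i:03d}",
                position_index=i,
                source="determinative",
            )
        )
    boundary = min(spec.ischemia_start_index, spec.n_rois)
    truth = PhantomGroundTruth(
        params=params,
        true_sufficient_set=set(range(boundary)),
        true_boundary_index=boundary,
    )
    return ref, dets, truth


def make_phantom_video(
    spec: PhantomSpec, width: int = 256, height: int = 64
) -> Tuple[VideoStack, np.ndarray, PhantomGroundTruth]:
    """Render the phantom as an 8-bit video of a horizontal bowel band.

    Each column follows the kinetic curve of the position it maps to
    (column c -> position floor(c * n_rois / width)); a low constant
    background fills the rest. Returns (video, band mask, ground truth).
    """
    if width < 16 or height < 16:
        raise ValueError("video must be at least 16x16")
    rng = np.random.default_rng(spec.seed)
    t = spec.times()
    n_frames = t.size
    params = [spec.position_params(i) for i in range(spec.n_rois)]
    col_pos = (np.arange(width) * spec.n_rois) // width
    pos_curves = np.stack([gamma_variate_values(p, t) for p in params])  # (n_rois, T)
    col_curves = pos_curves[col_pos]  # (width, T)

    background = 12.0
    gain = 200.0
    band = np.zeros((height, width), dtype=bool)
    band[height // 4: (3 * height) // 4, :] = True

    frames = np.empty((n_frames, height, width), dtype=np.uint8)
    chunk = max(1, int(2e7) // (height * width))
    for f0 in range(0, n_frames, chunk):
        f1 = min(f0 + chunk, n_frames)
        block = np.full((f1 - f0, height, width), background, dtype=np.float32)
        signal = (gain * col_curves[:, f0:f1].T)[:, None, :]  # (chunk, 1, width)
        block += np.where(band[None, :, :], signal, 0.0).astype(np.float32)
        if spec.noise_sigma > 0:
            block += rng.normal(0.0, spec.noise_sigma * gain, size=block.shape).astype(
                np.float32
            )
        frames[f0:f1] = np.clip(block, 0, 255).astype(np.uint8)

    white = np.full((height, width, 3), 90, dtype=np.uint8)
    white[band] = (200, 160, 150)  # pale bowel band on a dark field
    video = VideoStack(frames=frames, frame_rate=spec.rate_hz, white_light_frame=white)
    boundary = min(spec.ischemia_start_index, spec.n_rois)
    truth = PhantomGroundTruth(
        params=params,
        true_sufficient_set=set(range(boundary)),
        true_boundary_index=boundary,
    )
    return video, band, truth


def make_lactate(
    truth: PhantomGroundTruth,
    base_mgdl: float = 1.2,
    slope_mgdl: float = 2.0,
    noise_sigma: float = 0.1,
    seed: int = 0,
) -> Dict[str, np.ndarray]:
    """Simulated per-position tissue lactate rising with ischemic dilation.

    ``lactate_i = base + slope * (dilation_i - 1) + noise``; ratios are
    relative to position 0.
    """
    rng = np.random.default_rng(seed)
    base_rise = truth.params[0].peak_tp_s - truth.params[0].onset_t0_s
    dilation = np.array(
        [(p.peak_tp_s - p.onset_t0_s) / base_rise for p in truth.params]
    )
    lactate = base_mgdl + slope_mgdl * (dilation - 1.0)
    if noise_sigma > 0:
        lactate = lactate + rng.normal(0.0, noise_sigma, size=lactate.shape)
    lactate = np.maximum(lactate, 1e-6)
    return {
        "position_index": np.arange(len(truth.params)),
        "lactate_mgdl": lactate,
        "lactate_ratio": lactate / lactate[0],
    }
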