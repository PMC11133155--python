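"""Per-pixel (block-wise) recommendation and heatmap rendering.

The reference fit is applied to the curve of every pixel block inside an
annotated region; accepted blocks are classified by a histogram rule on
briskness (1/s): the 75th percentile of briskness over accepted blocks is
the anchor, green marks blocks at or above 75% of it, red marks blocks
below 25% of it or rejected, orange everything in between. Results render
as colour overlays on the co-registered white-light frame.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import imageio.v3 as iio
import matplotlib

matplotlib.use("Agg")
import numpy as np
from matplotlib import colormaps

from .curve_match import CurveFitResult, MatchConfig, ReferenceProfile, fit_batch
from .errors import UnquantifiableCurveError
from .preprocess import PreprocessConfig, preprocess_curve
from .signal_io import VideoStack, extract_pixel_curves

logger = logging.getLogger(__name__)

LABEL_OUTSIDE = 0
LABEL_INSUFFICIENT = 1
LABEL_BORDERLINE = 2
LABEL_SUFFICIENT = 3

LABEL_NAMES = {
    LABEL_OUTSIDE: "outside",
    LABEL_INSUFFICIENT: "insufficient",
    LABEL_BORDERLINE: "borderline",
    LABEL_SUFFICIENT: "sufficient",
}

_LABEL_COLOURS = {
    LABEL_SUFFICIENT: (0, 190, 60),
    LABEL_BORDERLINE: (255, 150, 0),
    LABEL_INSUFFICIENT: (220, 30, 30),
}


@dataclass
class ScaleFieldMap:
    """Per-block fit results over an annotated region."""

    blocks: Dict[Tuple[int, int], CurveFitResult]
    bin_size: int
    mask: np.ndarray
    frame_shape: Tuple[int, int]

    @property
    def grid_shape(self) -> Tuple[int, int]:
        h, w = self.frame_shape
        b = self.bin_size
        return ((h + b - 1) // b, (w + b - 1) // b)

    def _grid(self, getter, fill=np.nan) -> np.ndarray:
        out = np.full(self.grid_shape, fill, dtype=float)
        for (bi, bj), fit in self.blocks.items():
            out[bi, bj] = getter(fit)
        return out

    def scale_grid(self) -> np.ndarray:
        return self._grid(lambda f: f.scale_s)

    def briskness_grid(self) -> np.ndarray:
        return self._grid(lambda f: f.briskness if np.isfinite(f.scale_s) else np.nan)

    def agreement_grid(self) -> np.ndarray:
        return self._grid(lambda f: f.agreement)

    def accepted_grid(self) -> np.ndarray:
        return self._grid(lambda f: float(f.accepted), fill=0.0)


@dataclass
class PixelClassification:
    labels: np.ndarray  # block-grid int labels
    q75_briskness: Optional[float]
    bin_size: int
    frame_shape: Tuple[int, int]
    rule: dict = field(default_factory=dict)


@dataclass
class HeatmapOverlay:
    image: np.ndarray  # (H, W, 3) uint8
    legend: dict


def fit_all_pixels(
    profile: ReferenceProfile,
    video: VideoStack,
    mask: np.ndarray,
    match_cfg: Optional[MatchConfig] = None,
    pre_cfg: Optional[PreprocessConfig] = None,
    bin: int = 4,
) -> ScaleFieldMap:
    """Preprocess and fit the curve of every masked pixel block."""
    match_cfg = match_cfg or MatchConfig()
    pre_cfg = pre_cfg or PreprocessConfig()
    raw = extract_pixel_curves(video, mask, bin=bin)
    keys, prepped = [], []
    blocks: Dict[Tuple[int, int], CurveFitResult] = {}
    for key, curve in raw.items():
        try:
            prepped.append(preprocess_curve(curve, pre_cfg))
            keys.append(key)
        except UnquantifiableCurveError:
            blocks[key] = CurveFitResult(
                scale_s=np.nan, shift_tau_s=np.nan, agreement=0.0,
                diff_curve_area=np.nan, accepted=False, roi_id=curve.roi_id,
                position_index=curve.position_index,
                meta={"reason": "unquantifiable"},
            )
    if prepped:
        for key, fit in zip(keys, fit_batch(profile, prepped, match_cfg)):
            blocks[key] = fit
    return ScaleFieldMap(
        blocks=blocks, bin_size=bin,
        mask=np.asarray(mask, dtype=bool), frame_shape=video.frame_shape,
    )


def classify_field(
    field_map: ScaleFieldMap,
    sufficient_frac: float = 0.75,
    insufficient_frac: float = 0.25,
    rule_mode: str = "fraction_of_q75",
) -> PixelClassification:
    """Three-colour classification of the fitted field.

    ``fraction_of_q75`` (default): q75 = 75th percentile of briskness over
    accepted blocks (linear interpolation between order statistics);
    sufficient if briskness >= sufficient_frac * q75, insufficient if
    below insufficient_frac * q75 or rejected, borderline in between.
    ``percentile_rank``: insufficient below the 25th briskness percentile,
    sufficient at or above the 75th.
    """
    labels = np.full(field_map.grid_shape, LABEL_OUTSIDE, dtype=np.int8)
    accepted = {k: f for k, f in field_map.blocks.items() if f.accepted}
    if not accepted:
        warnings.warn("no accepted blocks; classifying entire region insufficient")
        for k in field_map.blocks:
            labels[k] = LABEL_INSUFFICIENT
        return PixelClassification(
            labels=labels, q75_briskness=None, bin_size=field_map.bin_size,
            frame_shape=field_map.frame_shape, rule={"mode": rule_mode},
        )
    brisk = np.array([f.briskness for f in accepted.values()])
    q75 = float(np.percentile(brisk, 75))
    if rule_mode == "fraction_of_q75":
        hi, lo = sufficient_frac * q75, insufficient_frac * q75
    elif rule_mode == "percentile_rank":
        hi, lo = float(np.percentile(brisk, 75)), float(np.percentile(brisk, 25))
    else:
        raise ValueError(f"unknown rule_mode {rule_mode!r}")
    for k, f in field_map.blocks.items():
        if not f.accepted:
            labels[k] = LABEL_INSUFFICIENT
        elif f.briskness >= hi:
            labels[k] = LABEL_SUFFICIENT
        elif f.briskness < lo:
            labels[k] = LABEL_INSUFFICIENT
        else:
            labels[k] = LABEL_BORDERLINE
    return PixelClassification(
        labels=labels, q75_briskness=q75, bin_size=field_map.bin_size,
        frame_shape=field_map.frame_shape,
        rule={"mode": rule_mode, "hi": hi, "lo": lo},
    )


def _as_rgb(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim == 2:
        frame = np.repeat(frame[..., None], 3, axis=2)
    return frame[..., :3].astype(np.uint8)


def _upsample_to(frame_shape: Tuple[int, int], grid: np.ndarray, bin_size: int) -> np.ndarray:
    up = np.repeat(np.repeat(grid, bin_size, axis=0), bin_size, axis=1)
    return up[: frame_shape[0], : frame_shape[1]]


def render_metric_heatmap(
    metric_grid: np.ndarray,
    white_light_frame: np.ndarray,
    bin_size: int = 1,
    cmap: str = "viridis",
    alpha: float = 0.45,
    label: str = "",
) -> HeatmapOverlay:
    """Colour-gradient overlay of a per-block metric on the white-light frame.

    Perceptually uniform map, low values purple and high values yellow;
    blocks with missing values leave the frame untouched.
    """
    base = _as_rgb(white_light_frame)
    h, w = base.shape[:2]
    finite = np.isfinite(metric_grid)
    if not finite.any():
        return HeatmapOverlay(image=base.copy(), legend={})
    vmin = float(np.nanmin(metric_grid))
    vmax = float(np.nanmax(metric_grid))
    span = vmax - vmin if vmax > vmin else 1.0
    norm = (metric_grid - vmin) / span
    colours = (colormaps[cmap](np.nan_to_num(norm))[..., :3] * 255).astype(np.uint8)
    up_col = _upsample_to((h, w), colours, bin_size)
    up_ok = _upsample_to((h, w), finite.astype(float), bin_size) > 0.5
    out = base.copy()
    blend = (1 - alpha) * base[up_ok] + alpha * up_col[up_ok]
    out[up_ok] = np.clip(blend, 0, 255).astype(np.uint8)
    legend = {"cmap": cmap, "vmin": vmin, "vmax": vmax, "label": label, "alpha": alpha}
    return HeatmapOverlay(image=out, legend=legend)


def render_recommendation_overlay(
    classification: PixelClassification,
    white_light_frame: np.ndarray,
    alpha: float = 0.45,
) -> HeatmapOverlay:
    """Green/orange/red label overlay; pixels outside the region untouched."""
    base = _as_rgb(white_light_frame)
    h, w = base.shape[:2]
    up_labels = _upsample_to((h, w), classification.labels.astype(float),
                             classification.bin_size).astype(np.int8)
    out = base.copy()
    for label, colour in _LABEL_COLOURS.items():
        sel = up_labels == label
        blend = (1 - alpha) * base[sel] + alpha * np.array(colour, dtype=float)
        out[sel] = np.clip(blend, 0, 255).astype(np.uint8)
    legend = {
        "colours": {LABEL_NAMES[k]: v for k, v in _LABEL_COLOURS.items()},
        "q75_briskness": classification.q75_briskness,
        "rule": classification.rule,
        "alpha": alpha,
    }
    return HeatmapOverlay(image=out, legend=legend)


def save_overlay(overlay: HeatmapOverlay, path) -> None:
    iio.imwrite(path, overlay.image)
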