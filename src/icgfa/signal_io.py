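"""Video stacks, ROI annotations and perfusion time series.

Reads multi-frame grayscale TIFF video with an optional YAML sidecar for
acquisition metadata and an optional co-registered white-light PNG,
stabilizes the stack by whole-frame translation against frame 0, and
extracts intensity-time curves for polyline-spaced ROIs or pixel blocks.

Conventions: coordinates are 0-based ``(row, col)`` with the origin at the
image top-left; time 0 is the first frame of the recording.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage
from skimage.draw import disk
from skimage.registration import phase_cross_correlation

from .errors import CurveFormatError, VideoFormatError

logger = logging.getLogger(__name__)

CURVE_COLUMNS = ["time_s", "roi_id", "position_index", "source", "intensity"]

DEFAULT_FRAME_RATE = 30.0


@dataclass
class PerfusionCurve:
    """One ROI's (or pixel block's) fluorescence intensity time series."""

    times_s: np.ndarray
    intensities: np.ndarray
    roi_id: str = "roi000"
    position_index: int = 0
    source: str = "determinative"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times_s.shape != self.intensities.shape:
            raise ValueError("times_s and intensities must have equal length")
        if self.times_s.size > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times_s must be strictly increasing")
        if self.source not in ("reference", "determinative"):
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0]) if self.times_s.size else 0.0

    @property
    def dt(self) -> float:
        """Sample spacing; only meaningful on a uniform grid."""
        if self.times_s.size < 2:
            raise ValueError("need at least 2 samples for a grid spacing")
        return float(self.times_s[1] - self.times_s[0])

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        if self.times_s.size < 3:
            return True
        d = np.diff(self.times_s)
        return bool(np.allclose(d, d[0], rtol=rtol, atol=1e-9))

    def replace(self, **kwargs) -> "PerfusionCurve":
        """Copy with selected fields replaced; metadata is shallow-copied."""
        out = {
            "times_s": self.times_s.copy(),
            "intensities": self.intensities.copy(),
            "roi_id": self.roi_id,
            "position_index": self.position_index,
            "source": self.source,
            "meta": dict(self.meta),
        }
        out.update(kwargs)
        return PerfusionCurve(**out)


@dataclass
class VideoStack:
    """Grayscale frame stack with acquisition metadata.

    ``offsets`` holds the per-frame ``(row, col)`` translations applied by
    :func:`stabilize`; ``None`` for an unstabilized stack.
    """

    frames: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE
    white_light_frame: Optional[np.ndarray] = None
    offsets: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None, ...]
        if self.frames.ndim != 3:
            raise VideoFormatError(
                f"expected a (frames, rows, cols) stack, got ndim={self.frames.ndim}"
            )
        if self.frame_rate <= 0:
            raise VideoFormatError("frame_rate must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> Tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class ROILine:
    """User-drawn polyline along the bowel plus ROI spacing parameters.

    Vertices are ordered proximal end first, in ``(row, col)`` pixel units.
    """

    vertices: np.ndarray
    spacing_px: float
    roi_radius_px: float = 8.0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n>=2, 2) array of (row, col)")
        if self.spacing_px <= 0:
            raise ValueError("spacing_px must be > 0")
        if self.roi_radius_px <= 0:
            raise ValueError("roi_radius_px must be > 0")

    @property
    def length_px(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)))

    def roi_centres(self) -> np.ndarray:
        """Equal arc-length ROI centres along the polyline, start included."""
        seg = np.diff(self.vertices, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        total = cum[-1]
        distances = np.arange(0.0, total + 1e-9, self.spacing_px)
        rows = np.interp(distances, cum, self.vertices[:, 0])
        cols = np.interp(distances, cum, self.vertices[:, 1])
        return np.column_stack([rows, cols])


def _sidecar_paths(path: Path) -> Tuple[Path, Path]:
    return path.with_suffix(".yaml"), path.with_name(path.stem + "_wl.png")


def read_video(path) -> VideoStack:
    """Read a multi-frame grayscale TIFF plus optional sidecars.

    Frame rate comes from a ``<stem>.yaml`` sidecar (key ``frame_rate``,
    default 30); a co-registered white-light frame is picked up from
    ``<stem>_wl.png`` when present.
    """
    path = Path(path)
    if not path.exists():
        raise VideoFormatError(f"no such file: {path}")
    try:
        frames = tifffile.imread(path)
    except Exception as exc:  # truncated/corrupt container
        raise VideoFormatError(f"cannot read TIFF {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None, ...]
    if frames.ndim != 3 or frames.dtype == object:
        raise VideoFormatError(
            f"{path}: expected a grayscale frame stack of identical shapes"
        )
    frame_rate = DEFAULT_FRAME_RATE
    meta_path, wl_path = _sidecar_paths(path)
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
        frame_rate = float(meta.get("frame_rate", DEFAULT_FRAME_RATE))
    white = None
    if wl_path.exists():
        white = np.asarray(iio.imread(wl_path))
    return VideoStack(frames=frames, frame_rate=frame_rate, white_light_frame=white)


def write_video(video: VideoStack, path) -> None:
    """Write a stack as multi-frame TIFF with YAML/PNG sidecars."""
    path = Path(path)
    tifffile.imwrite(path, video.frames, photometric="minisblack")
    meta_path, wl_path = _sidecar_paths(path)
    with open(meta_path, "w") as fh:
        yaml.safe_dump({"frame_rate": float(video.frame_rate)}, fh)
    if video.white_light_frame is not None:
        iio.imwrite(wl_path, np.asarray(video.white_light_frame, dtype=np.uint8))


def stabilize(video: VideoStack) -> VideoStack:
    """Register every frame to frame 0 by whole-frame integer translation.

    Cross-correlation registration; frame 0 is never moved. Degenerate
    stacks (uniform or all-zero frames) come back unchanged with zero
    offsets and a logged warning.
    """
    frames = video.frames
    n = frames.shape[0]
    offsets = np.zeros((n, 2), dtype=float)
    ref = frames[0].astype(float)
    if ref.std() == 0:
        logger.warning("stabilize: frame 0 has no texture; returning input unchanged")
        return VideoStack(frames.copy(), video.frame_rate, video.white_light_frame, offsets)
    out = frames.copy()
    for k in range(1, n):
        moving = frames[k].astype(float)
        if moving.std() == 0:
            logger.warning("stabilize: frame %d has no texture; zero offset", k)
            continue
        shift, _, _ = phase_cross_correlation(ref, moving, upsample_factor=1)
        shift = np.round(shift).astype(int)
        offsets[k] = shift
        out[k] = ndimage.shift(frames[k], shift, order=0, mode="constant", cval=0)
    return VideoStack(out, video.frame_rate, video.white_light_frame, offsets)


def extract_roi_curves(
    video: VideoStack,
    line: ROILine,
    source: str = "determinative",
) -> List[PerfusionCurve]:
    """Mean-intensity curve per disc-shaped ROI spaced along the polyline.

    ROI centres whose disc falls entirely out of frame are dropped with a
    log message; ``position_index`` increases from the line's first vertex.
    """
    shape = video.frame_shape
    times = video.times_s
    curves: List[PerfusionCurve] = []
    for idx, centre in enumerate(line.roi_centres()):
        rr, cc = disk(tuple(centre), line.roi_radius_px, shape=shape)
        if rr.size == 0:
            logger.warning("ROI %d at %s lies outside the frame; dropped", idx, centre)
            continue
        intensities = video.frames[:, rr, cc].mean(axis=1)
        curves.append(
            PerfusionCurve(
                times_s=times,
                intensities=intensities,
                roi_id=f"roi{idx:03d}",
                position_index=idx,
                source=source,
                meta={"centre": tuple(float(c) for c in centre)},
            )
        )
    return curves


def extract_pixel_curves(
    video: VideoStack,
    mask: np.ndarray,
    bin: int = 4,
    source: str = "determinative",
) -> Dict[Tuple[int, int], PerfusionCurve]:
    """One mean curve per ``bin``x``bin`` block of masked pixels.

    Block (0, 0) sits at the image top-left; blocks with no masked pixel
    are omitted. ``bin=1`` yields literal per-pixel curves.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != video.frame_shape:
        raise ValueError("mask shape must equal the frame shape")
    if bin < 1:
        raise ValueError("bin must be >= 1")
    times = video.times_s
    h, w = mask.shape
    out: Dict[Tuple[int, int], PerfusionCurve] = {}
    for bi in range((h + bin - 1) // bin):
        r0, r1 = bi * bin, min((bi + 1) * bin, h)
        for bj in range((w + bin - 1) // bin):
            c0, c1 = bj * bin, min((bj + 1) * bin, w)
            block_mask = mask[r0:r1, c0:c1]
            if not block_mask.any():
                continue
            block = video.frames[:, r0:r1, c0:c1]
            vals = block.reshape(video.n_frames, -1)[:, block_mask.ravel()]
            out[(bi, bj)] = PerfusionCurve(
                times_s=times,
                intensities=vals.mean(axis=1),
                roi_id=f"blk_{bi:03d}_{bj:03d}",
                position_index=bj,
                source=source,
                meta={"block": (bi, bj), "n_pixels": int(block_mask.sum())},
            )
    return out


def write_curves(curves: Sequence[PerfusionCurve], path) -> None:
    """Serialize curves to the canonical long-format CSV."""
    records = []
    for c in curves:
        records.append(
            pd.DataFrame(
                {
                    "time_s": c.times_s,
                    "roi_id": c.roi_id,
                    "position_index": c.position_index,
                    "source": c.source,
                    "intensity": c.intensities,
                }
            )
        )
    if records:
        df = pd.concat(records, ignore_index=True)[CURVE_COLUMNS]
    else:
        df = pd.DataFrame(columns=CURVE_COLUMNS)
    df.to_csv(path, index=False)


def read_curves(path) -> List[PerfusionCurve]:
    """Read curves from CSV; per-ROI unsorted times are re-sorted with a warning."""
    df = pd.read_csv(path)
    for col in CURVE_COLUMNS:
        if col not in df.columns:
            raise CurveFormatError(f"missing column: {col}")
    curves = []
    for roi_id, grp in df.groupby("roi_id", sort=False):
        times = grp["time_s"].to_numpy(dtype=float)
        if times.size > 1 and np.any(np.diff(times) <= 0):
            logger.warning("curves for %s not sorted by time; re-sorting", roi_id)
            grp = grp.sort_values("time_s")
            times = grp["time_s"].to_numpy(dtype=float)
        curves.append(
            PerfusionCurve(
                times_s=times,
                intensities=grp["intensity"].to_numpy(dtype=float),
                roi_id=str(roi_id),
                position_index=int(grp["position_index"].iloc[0]),
                source=str(grp["source"].iloc[0]),
            )
        )
    return curves
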