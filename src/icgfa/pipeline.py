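"""End-to-end glue: raw curves -> preprocessing -> fits -> recommendation."""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

from .curve_match import CurveFitResult, MatchConfig, ReferenceProfile, fit_batch
from .preprocess import PreprocessConfig, preprocess_curve
from .roi_recommender import (
    RecommendationResult,
    ROISeriesResult,
    classify_sufficiency,
)
from .signal_io import PerfusionCurve


def run_roi_pipeline(
    reference: PerfusionCurve,
    determinatives: Sequence[PerfusionCurve],
    pre_cfg: Optional[PreprocessConfig] = None,
    match_cfg: Optional[MatchConfig] = None,
    segment_type: str = "large_bowel",
    rel_threshold: float = 0.95,
    spacing_cm: float = 2.0,
) -> Tuple[RecommendationResult, List[CurveFitResult]]:
    """Preprocess reference and determinative curves, fit, and recommend."""
    pre_cfg = pre_cfg or PreprocessConfig()
    match_cfg = match_cfg or MatchConfig()
    profile = ReferenceProfile(
        curve=preprocess_curve(reference, pre_cfg), segment_type=segment_type
    )
    dets = [preprocess_curve(d, pre_cfg) for d in determinatives]
    fits = fit_batch(profile, dets, match_cfg)
    series = ROISeriesResult(fits=fits, spacing_cm=spacing_cm)
    rec = classify_sufficiency(series, rel_threshold=rel_threshold)
    return rec, fits
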