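"""ROI-level transection recommendation.

Among accepted fits, sufficiency is granted to the briskest determinative
curves (or those at least 95% as fast as the briskest, on briskness = 1/s);
the recommended transection site is the most distal sufficient ROI. When no
fit is accepted the result is an explicit no-recommendation — a valid
outcome, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Set

from .curve_match import CurveFitResult


@dataclass
class ROISeriesResult:
    """Ordered per-ROI fit results, proximal to distal."""

    fits: List[CurveFitResult]
    spacing_cm: float = 2.0

    def __post_init__(self) -> None:
        if self.spacing_cm <= 0:
            raise ValueError("spacing_cm must be > 0")
        pos = [f.position_index for f in self.fits]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("fits must be ordered by strictly increasing position")


@dataclass
class RecommendationResult:
    status: str  # "recommended" | "no_recommendation"
    sufficient_set: Set[int] = field(default_factory=set)
    recommended_index: Optional[int] = None
    max_briskness: Optional[float] = None
    per_roi: List[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "recommended_index": self.recommended_index,
            "sufficient_set": sorted(self.sufficient_set),
            "max_briskness": self.max_briskness,
            "per_roi": self.per_roi,
        }


def classify_sufficiency(
    series: ROISeriesResult, rel_threshold: float = 0.95
) -> RecommendationResult:
    """Label sufficiency per ROI and pick the most distal sufficient one.

    Only accepted fits can be sufficient; a fit is sufficient when its
    briskness reaches ``rel_threshold`` times the maximum briskness among
    accepted fits.
    """
    if not series.fits:
        raise ValueError("empty ROI series")
    accepted = [f for f in series.fits if f.accepted]
    per_roi = [f.to_dict() for f in series.fits]
    if not accepted:
        return RecommendationResult(status="no_recommendation", per_roi=per_roi)
    max_brisk = max(f.briskness for f in accepted)
    sufficient = {
        f.position_index for f in accepted if f.briskness >= rel_threshold * max_brisk
    }
    for row in per_roi:
        row["sufficient"] = row["position_index"] in sufficient
    return RecommendationResult(
        status="recommended",
        sufficient_set=sufficient,
        recommended_index=max(sufficient),
        max_briskness=max_brisk,
        per_roi=per_roi,
    )


def jaccard_index(zone_a: Set[int], zone_b: Set[int]) -> float:
    """|A n B| / |A u B|; 1.0 when both zones are empty (convention)."""
    a, b = set(zone_a), set(zone_b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def expert_zone(expert_position: int, mode: str = "proximal_run") -> Set[int]:
    """Construct the expert's implied safe zone from the single marked ROI.

    ``proximal_run`` includes every ROI from the proximal end through the
    marked site (marking a site implicitly certifies everything proximal);
    ``point`` is the marked ROI alone.
    """
    if mode == "point":
        return {expert_position}
    if mode == "proximal_run":
        return set(range(expert_position + 1))
    raise ValueError(f"unknown expert_zone_mode {mode!r}")


def evaluate_against_expert(
    rec: RecommendationResult, expert_position: int
) -> dict:
    """Containment of the expert site plus whether a more distal safe
    alternative was recommended."""
    contained = expert_position in rec.sufficient_set
    distal = (
        rec.recommended_index is not None
        and rec.recommended_index > expert_position
    )
    return {"contained": contained, "distal_alternative": distal}
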