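"""Patient-calibrated curve matching.

The reference perfusion curve is adapted to each determinative curve by
scaling and shifting along the time axis only (amplitude is never fitted):
the candidate fit is ``ref((t - tau) / s)``, taken as 0 outside the
reference's recorded domain. Agreement is one minus the L1 area
disagreement relative to the determinative curve's area; fits with
agreement below the acceptance threshold (default 0.85) are rejected.

``scale_s > 1`` means the reference had to be broadened, i.e. the
determinative perfusion is slower than baseline; briskness is ``1/s``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.optimize import minimize, minimize_scalar

from .errors import ConfigError, UnquantifiableCurveError
from .signal_io import PerfusionCurve

logger = logging.getLogger(__name__)

_TIE_EPS = 1e-12


@dataclass
class ReferenceProfile:
    """The patient's own baseline perfusion curve, preprocessed."""

    curve: PerfusionCurve
    segment_type: str = "large_bowel"
    patient_id: str = "anon"

    def __post_init__(self) -> None:
        if self.segment_type not in ("small_bowel", "large_bowel"):
            raise ValueError(f"unknown segment_type {self.segment_type!r}")


@dataclass
class MatchConfig:
    s_min: float = 0.25
    s_max: float = 4.0
    s_steps: int = 121
    tau_min_s: float = -60.0
    tau_max_s: float = 60.0
    tau_step_s: float = 0.5
    accept_threshold: float = 0.85
    objective: str = "area"  # or "ncc"
    s_refine_tol: float = 1e-3

    def __post_init__(self) -> None:
        if not (0 < self.s_min < self.s_max):
            raise ConfigError("require 0 < s_min < s_max")
        if self.s_steps < 2:
            raise ConfigError("s_steps must be >= 2")
        if self.tau_max_s < self.tau_min_s:
            raise ConfigError("tau_max_s must be >= tau_min_s")
        if self.tau_step_s <= 0:
            raise ConfigError("tau_step_s must be > 0")
        if not (0 < self.accept_threshold < 1):
            raise ConfigError("accept_threshold must lie in (0, 1)")
        if self.objective not in ("area", "ncc"):
            raise ConfigError(f"unknown objective {self.objective!r}")

    def s_grid(self) -> np.ndarray:
        return np.geomspace(self.s_min, self.s_max, self.s_steps)

    @classmethod
    def from_dict(cls, d: dict) -> "MatchConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class CurveFitResult:
    """Outcome of fitting the reference to one determinative curve."""

    scale_s: float
    shift_tau_s: float
    agreement: float
    diff_curve_area: float
    accepted: bool
    roi_id: str = "roi000"
    position_index: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def briskness(self) -> float:
        """Relative speed of the determinative curve versus baseline (1/s)."""
        return 1.0 / self.scale_s

    def to_dict(self) -> dict:
        return {
            "roi_id": self.roi_id,
            "position_index": self.position_index,
            "scale_s": self.scale_s,
            "shift_tau_s": self.shift_tau_s,
            "agreement": self.agreement,
            "diff_curve_area": self.diff_curve_area,
            "accepted": self.accepted,
            "briskness": self.briskness,
        }


def _fitted_reference(ref: PerfusionCurve, t: np.ndarray, s: float, tau: float) -> np.ndarray:
    return np.interp((t - tau) / s, ref.times_s, ref.intensities, left=0.0, right=0.0)


def agreement(
    ref: PerfusionCurve,
    det: PerfusionCurve,
    s: float,
    tau: float,
    objective: str = "area",
) -> float:
    """Similarity between the scaled-and-shifted reference and a determinative curve.

    Area objective: ``1 - integral |ref((t-tau)/s) - det(t)| / integral det(t)``
    over the determinative support, clipped to [0, 1]. The alternative
    ``ncc`` objective is the (clipped) normalized cross-correlation.
    """
    if s <= 0:
        raise ValueError("scale must be > 0")
    t = det.times_s
    d = det.intensities
    fitted = _fitted_reference(ref, t, s, tau)
    if objective == "area":
        denom = float(d.sum())
        if denom <= 0:
            raise UnquantifiableCurveError("unquantifiable determinative curve")
        return float(np.clip(1.0 - np.abs(fitted - d).sum() / denom, 0.0, 1.0))
    norm = np.linalg.norm(fitted) * np.linalg.norm(d)
    if norm == 0:
        if np.linalg.norm(d) == 0:
            raise UnquantifiableCurveError("unquantifiable determinative curve")
        return 0.0
    return float(np.clip(float(fitted @ d) / norm, 0.0, 1.0))


def accept_fit(result: CurveFitResult, cfg: MatchConfig) -> bool:
    """Acceptance rule: agreement at or above the threshold (>= convention)."""
    return result.agreement >= cfg.accept_threshold


def interpret_scale(result: CurveFitResult, tol: float = 0.02) -> str:
    """Read the fitted scale: narrowing (s<1) means brisker baseline perfusion
    relative to the determinative curve; broadening (s>1) means slower."""
    if abs(result.scale_s - 1.0) <= tol:
        return "equal"
    return "brisker" if result.scale_s < 1.0 else "slower"


def _tau_grid_samples(cfg: MatchConfig, dt: float) -> np.ndarray:
    """Shift grid snapped to whole samples of the determinative grid."""
    k_step = max(int(round(cfg.tau_step_s / dt)), 1)
    k_min = int(round(cfg.tau_min_s / dt))
    k_max = int(round(cfg.tau_max_s / dt))
    ks = np.arange(k_min, k_max + 1, k_step)
    if ks.size == 0:
        raise ConfigError("empty shift grid")
    return ks


def _grid_search(
    ref: PerfusionCurve,
    dets: Sequence[PerfusionCurve],
    cfg: MatchConfig,
) -> List[tuple]:
    """Exhaustive (s, tau) grid search, vectorized over the shift axis.

    Returns per-determinative-curve ``(agreement, s, tau)`` for the best
    grid cell; ties broken by smallest ``|tau|`` then ``s`` nearest 1.
    """
    t = dets[0].times_s
    n = t.size
    dt = dets[0].dt
    D = np.stack([d.intensities for d in dets])  # (m, n)
    m = D.shape[0]
    sums = D.sum(axis=1)
    if cfg.objective == "area" and np.any(sums <= 0):
        bad = [dets[i].roi_id for i in np.nonzero(sums <= 0)[0]]
        raise UnquantifiableCurveError(f"unquantifiable determinative curve(s): {bad}")
    d_norms = np.linalg.norm(D, axis=1)

    s_grid = cfg.s_grid()
    ks = _tau_grid_samples(cfg, dt)
    k_max = int(ks.max())
    k_min = int(ks.min())
    taus = ks * dt
    tau_pref = np.abs(taus)  # tie-break key 1

    # pad so that g[(i - k) + pad] = ref((i - k) * dt / s) for all needed i - k
    pad_lo = max(k_max, 0)
    j = np.arange(-pad_lo, n - min(k_min, 0))
    rows = pad_lo - ks  # window start per tau

    best_val = np.full(m, -np.inf)
    best_s = np.ones(m)
    best_tau = np.zeros(m)
    for s in s_grid:
        g = np.interp(j * dt / s, ref.times_s, ref.intensities, left=0.0, right=0.0)
        windows = sliding_window_view(g, n)[rows]  # (n_tau, n)
        if cfg.objective == "area":
            cost = np.abs(windows[:, None, :] - D[None, :, :]).sum(axis=2)
            vals = np.clip(1.0 - cost / sums[None, :], 0.0, 1.0)  # (n_tau, m)
        else:
            w_norm = np.linalg.norm(windows, axis=1)
            denom = np.where(w_norm[:, None] * d_norms[None, :] == 0, np.inf,
                             w_norm[:, None] * d_norms[None, :])
            vals = np.clip((windows @ D.T) / denom, 0.0, 1.0)
        # best tau per det at this s, tie-broken by smallest |tau|
        col_max = vals.max(axis=0)
        masked_pref = np.where(vals >= col_max[None, :] - _TIE_EPS,
                               tau_pref[:, None], np.inf)
        tau_idx = masked_pref.argmin(axis=0)
        cand_val = vals[tau_idx, np.arange(m)]
        cand_tau = taus[tau_idx]
        better = cand_val > best_val + _TIE_EPS
        tied = np.abs(cand_val - best_val) <= _TIE_EPS
        tie_win = tied & (
            (np.abs(cand_tau) < np.abs(best_tau) - _TIE_EPS)
            | (
                (np.abs(np.abs(cand_tau) - np.abs(best_tau)) <= _TIE_EPS)
                & (np.abs(s - 1.0) < np.abs(best_s - 1.0) - _TIE_EPS)
            )
        )
        upd = better | tie_win
        best_val[upd] = cand_val[upd]
        best_s[upd] = s
        best_tau[upd] = cand_tau[upd]
    return [(float(best_val[i]), float(best_s[i]), float(best_tau[i])) for i in range(m)]


def _refine(
    ref: PerfusionCurve,
    det: PerfusionCurve,
    cfg: MatchConfig,
    s0: float,
    tau0: float,
    val0: float,
) -> tuple:
    """Golden-section (bounded scalar) refinement around the best grid cell."""
    s_grid = cfg.s_grid()
    dt = det.dt
    idx = int(np.argmin(np.abs(s_grid - s0)))
    s_lo = s_grid[max(idx - 1, 0)]
    s_hi = s_grid[min(idx + 1, s_grid.size - 1)]
    tau_half = max(cfg.tau_step_s, dt)
    best = (val0, s0, tau0)
    for _ in range(2):
        _, s_cur, tau_cur = best
        res = minimize_scalar(
            lambda s: -agreement(ref, det, s, tau_cur, cfg.objective),
            bounds=(s_lo, s_hi),
            method="bounded",
            options={"xatol": cfg.s_refine_tol},
        )
        if -res.fun > best[0]:
            best = (float(-res.fun), float(res.x), tau_cur)
        _, s_cur, tau_cur = best
        res = minimize_scalar(
            lambda tau: -agreement(ref, det, s_cur, tau, cfg.objective),
            bounds=(
                max(tau_cur - tau_half, cfg.tau_min_s),
                min(tau_cur + tau_half, cfg.tau_max_s),
            ),
            method="bounded",
            options={"xatol": dt * 1e-2},
        )
        if -res.fun > best[0]:
            best = (float(-res.fun), s_cur, float(res.x))
    # joint polish: the objective has a correlated (s, tau) valley that
    # coordinate-wise refinement alone descends slowly
    _, s_cur, tau_cur = best
    res = minimize(
        lambda x: -agreement(ref, det, float(np.exp(x[0])), float(x[1]), cfg.objective),
        x0=np.array([np.log(s_cur), tau_cur]),
        method="Nelder-Mead",
        options={"xatol": cfg.s_refine_tol / 4, "fatol": 1e-10, "maxiter": 200},
    )
    s_nm = float(np.exp(res.x[0]))
    tau_nm = float(res.x[1])
    if (
        -res.fun > best[0]
        and cfg.s_min <= s_nm <= cfg.s_max
        and cfg.tau_min_s <= tau_nm <= cfg.tau_max_s
    ):
        best = (float(-res.fun), s_nm, tau_nm)
    return best


def fit_batch(
    profile: ReferenceProfile,
    dets: Sequence[PerfusionCurve],
    cfg: Optional[MatchConfig] = None,
) -> List[CurveFitResult]:
    """Fit the reference to every determinative curve on a shared time grid.

    All determinative curves must be preprocessed onto the same uniform
    grid. Deterministic: grid search plus bounded scalar refinement.
    """
    cfg = cfg or MatchConfig()
    if not dets:
        return []
    t0 = dets[0].times_s
    for d in dets:
        if not d.is_uniform():
            raise ValueError(f"{d.roi_id}: determinative curve must be on a uniform grid")
        if d.times_s.shape != t0.shape or not np.allclose(d.times_s, t0):
            raise ValueError("all determinative curves must share one time grid")
    ref = profile.curve
    coarse = _grid_search(ref, dets, cfg)
    results = []
    dt = dets[0].dt
    for det, (val, s, tau) in zip(dets, coarse):
        val, s, tau = _refine(ref, det, cfg, s, tau, val)
        fitted = _fitted_reference(ref, det.times_s, s, tau)
        a_det = float(det.intensities.sum()) * dt
        a_ref = float(fitted.sum()) * dt
        diff_area = abs(a_ref - a_det) / a_det if a_det > 0 else np.nan
        res = CurveFitResult(
            scale_s=s,
            shift_tau_s=tau,
            agreement=val,
            diff_curve_area=diff_area,
            accepted=False,
            roi_id=det.roi_id,
            position_index=det.position_index,
            meta={"objective": cfg.objective},
        )
        res.accepted = accept_fit(res, cfg)
        results.append(res)
    return results


def fit_reference(
    profile: ReferenceProfile,
    det: PerfusionCurve,
    cfg: Optional[MatchConfig] = None,
) -> CurveFitResult:
    """Fit the patient's reference profile to a single determinative curve."""
    return fit_batch(profile, [det], cfg)[0]
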