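"""Spearman rank-correlation reporting with interpretation bands.

Pairwise-complete Spearman rho with average ranks for ties; two-tailed
p-values via the t approximation for n > 10 and exact permutation for
n <= 10. |rho| is labelled with half-open bands:
[0, 0.1) negligible, [0.1, 0.4) weak, [0.4, 0.7) moderate,
[0.7, 0.9) strong, [0.9, 1] very strong.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import factorial
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

BANDS = [
    (0.1, "negligible"),
    (0.4, "weak"),
    (0.7, "moderate"),
    (0.9, "strong"),
    (np.inf, "very strong"),
]


def band_label(rho: float) -> str:
    if not np.isfinite(rho):
        return "undefined"
    a = abs(rho)
    for edge, name in BANDS:
        if a < edge:
            return name
    return "very strong"


@dataclass
class CorrelationReport:
    rho: pd.DataFrame
    p: pd.DataFrame
    labels: pd.DataFrame
    n: pd.DataFrame

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.p < alpha

    def to_csv(self, path) -> None:
        """Matrix layout with a `*` appended for p < 0.05."""
        out = self.rho.round(2).astype(object)
        star = (self.p < 0.05) & np.isfinite(self.rho)
        for c in out.columns:
            out[c] = [
                f"{v:.2f}{'*' if s else ''}" if isinstance(v, float) and np.isfinite(v) else ""
                for v, s in zip(self.rho[c], star[c])
            ]
        out.to_csv(path)


def _exact_perm_p(rx: np.ndarray, ry: np.ndarray, rho: float) -> float:
    """Two-tailed exact permutation p for Spearman rho, n <= 10."""
    n = rx.size
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    total = factorial(n)
    count = 0
    chunk = 200_000
    perms = itertools.permutations(ry_c)
    while True:
        block = np.array(list(itertools.islice(perms, chunk)))
        if block.size == 0:
            break
        rhos = block @ rx_c / denom
        count += int(np.sum(np.abs(rhos) >= abs(rho) - 1e-12))
    return count / total


def spearman_pair(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, int]:
    """(rho, two-tailed p, n) on pairwise-complete observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        return np.nan, np.nan, n
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan, n
    rx = stats.rankdata(x)  # average ranks for ties
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 10:
        p = _exact_perm_p(rx, ry, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2 * stats.t.sf(abs(t), n - 2))
    return rho, p, n


def spearman_matrix(table: pd.DataFrame) -> CorrelationReport:
    """Full symmetric Spearman matrix over the numeric columns of a table.

    Constant or too-sparse variables get NaN rho (flagged via the
    ``undefined`` label); the diagonal is exactly 1 with p = 0.
    """
    cols = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    k = len(cols)
    rho = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        xi = table[cols[i]].to_numpy(dtype=float)
        rho[i, i], p[i, i] = 1.0, 0.0
        n[i, i] = int(np.isfinite(xi).sum())
        for jj in range(i + 1, k):
            r, pv, nn = spearman_pair(xi, table[cols[jj]].to_numpy(dtype=float))
            rho[i, jj] = rho[jj, i] = r
            p[i, jj] = p[jj, i] = pv
            n[i, jj] = n[jj, i] = nn
    labels = np.vectorize(band_label)(rho)
    mk = lambda a: pd.DataFrame(a, index=cols, columns=cols)
    return CorrelationReport(rho=mk(rho), p=mk(p), labels=mk(labels), n=mk(n))


def validation_run(
    metrics_df: pd.DataFrame,
    lactate: Optional[dict] = None,
    highlight_threshold: float = 0.4,
) -> Tuple[CorrelationReport, pd.DataFrame]:
    """Cross-correlate fit outputs, conventional descriptors and lactate.

    Returns the full report plus a summary of pairs reaching at least
    moderate correlation (|rho| >= 0.4, self-pairs excluded).
    """
    df = metrics_df.copy()
    if lactate is not None:
        lac = pd.DataFrame(lactate)
        df = df.merge(lac, on="position_index", how="left")
    preferred = [
        "lactate_mgdl", "lactate_ratio",
        "scale_s", "diff_curve_area", "fit_peak", "fit_accepted",
        "upslope", "t_half_s", "fmax", "tmax_s", "downslope",
        "t50_s", "f50", "d50", "t100_s", "f100", "d100", "tr",
        "centre_of_mass_s",
    ]
    cols = [c for c in preferred if c in df.columns]
    report = spearman_matrix(df[cols])
    rows = []
    seen = set()
    for a in cols:
        for b in cols:
            if a == b or (b, a) in seen:
                continue
            seen.add((a, b))
            r = report.rho.loc[a, b]
            if np.isfinite(r) and abs(r) >= highlight_threshold:
                rows.append(
                    {
                        "var_a": a, "var_b": b, "rho": r,
                        "p": report.p.loc[a, b],
                        "label": report.labels.loc[a, b],
                        "n": report.n.loc[a, b],
                    }
                )
    summary = pd.DataFrame(rows, columns=["var_a", "var_b", "rho", "p", "label", "n"])
    return report, summary
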