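"""Empirical-tail outlier detection in fixed, non-overlapping windows.

The genome is tiled with half-open windows [k*w, (k+1)*w) anchored at
coordinate 0.  The score threshold is a pure order statistic — the
nearest-rank (1 - tail) empirical quantile of |score| over all scanned
SNPs of that population — so a window qualifies when it holds at least
``min_top`` SNPs at or above the threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["WindowResult", "window_outliers", "cross_population_windows"]


@dataclass
class WindowResult:
    """Qualifying windows for one population."""

    frame: pd.DataFrame  # chrom, window_start, window_end, n_snps, n_top, top_snp_ids
    threshold: float
    window_bp: int
    tail: float


def empirical_tail_threshold(abs_scores: np.ndarray, tail: float) -> float:
    """Nearest-rank (1 - tail) quantile: the ceil(n*(1-tail))-th order statistic."""
    x = np.sort(np.asarray(abs_scores, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("no scores to form a threshold from")
    k = max(1, math.ceil(n * (1.0 - tail)))
    return float(x[k - 1])


def window_outliers(
    scores: pd.DataFrame,
    window_bp: int = 100_000,
    tail: float = 0.001,
    min_top: int = 2,
    score_col: str = "ihs",
) -> WindowResult:
    """Windows holding at least ``min_top`` tail-outlier SNPs.

    ``scores`` needs columns chrom, pos, snp_id and a standardized score
    column (|score| is ranked).  A SNP exactly on a window boundary
    belongs to the right window.
    """
    if not 0.0 < tail < 0.5:
        raise ValueError("tail must be in (0, 0.5)")
    df = scores[scores[score_col].notna()].copy()
    absval = df[score_col].abs().to_numpy()
    if absval.size < 1.0 / tail:
        warnings.warn(
            f"only {absval.size} scores for a {tail:g} tail; "
            "threshold is the stated order statistic but poorly resolved"
        )
    threshold = empirical_tail_threshold(absval, tail)
    df["window"] = df["pos"].to_numpy() // window_bp
    df["is_top"] = absval >= threshold
    rows = []
    for (chrom, win), grp in df.groupby(["chrom", "window"], sort=True):
        n_top = int(grp["is_top"].sum())
        if n_top >= min_top:
            top = grp[grp["is_top"]].sort_values("pos")
            rows.append(
                {
                    "chrom": chrom,
                    "window_start": int(win * window_bp),
                    "window_end": int((win + 1) * window_bp),
                    "n_snps": len(grp),
                    "n_top": n_top,
                    "top_snp_ids": ";".join(map(str, top["snp_id"])),
                    "top_scores": ";".join(f"{v:.3f}" for v in top[score_col]),
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "chrom", "window_start", "window_end", "n_snps", "n_top",
            "top_snp_ids", "top_scores",
        ],
    )
    return WindowResult(frame=frame, threshold=threshold, window_bp=window_bp, tail=tail)


def cross_population_windows(
    results: dict[str, WindowResult], min_pops: int = 2
) -> pd.DataFrame:
    """Windows qualifying in at least ``min_pops`` populations.

    All results must share the windowing grid.  Output rows carry the
    per-population top-SNP lists side by side.
    """
    widths = {r.window_bp for r in results.values()}
    if len(widths) > 1:
        raise ValueError("window grids differ between populations")
    merged: dict[tuple, dict] = {}
    for pop, res in results.items():
        for r in res.frame.itertuples():
            key = (r.chrom, r.window_start, r.window_end)
            merged.setdefault(key, {})[pop] = r.top_snp_ids
    rows = []
    for key in sorted(merged, key=lambda k: (str(k[0]), k[1])):
        pops = merged[key]
        if len(pops) >= min_pops:
            rows.append(
                {
                    "chrom": key[0],
                    "window_start": key[1],
                    "window_end": key[2],
                    "n_populations": len(pops),
                    "populations": ";".join(sorted(pops)),
                    "top_snp_ids": "|".join(
                        f"{p}:{pops[p]}" for p in sorted(pops)
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "window_start", "window_end", "n_populations",
            "populations", "top_snp_ids",
        ],
    )
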