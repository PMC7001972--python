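"""Integrated haplotype score (iHS) scan.

The unstandardized score at a SNP is ln(iHH_A / iHH_D) — negative when the
haplotypes around the derived allele are the longer ones, the signature of
an ongoing sweep on the derived allele.  Because its null distribution
depends on allele frequency, raw scores are binned by derived-allele
frequency and z-standardized within each bin; the standardized score is
approximately standard normal so two-sided Gaussian p-values apply:

    -log10 p = -log10( 2 * Phi(-|iHS|) )
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ehh import DEFAULT_EHH_FLOOR, InsufficientCarriersError, integrated_ehh
from .panel import ANC_UNKNOWN, HaplotypePanel

__all__ = [
    "ScoreTable", "ihs_scan", "unstandardized_ihs", "standardize",
    "score_to_neglog10p", "significance_threshold", "significant_snps",
    "coincidence", "DEFAULT_MAF_RANGE",
]

DEFAULT_MAF_RANGE = (0.05, 0.95)
DEFAULT_BIN_WIDTH = 0.025
DEFAULT_MIN_BIN_N = 10


@dataclass
class ScoreTable:
    """Per-SNP score table plus the frequency-bin statistics used.

    ``frame`` columns: snp_id, chrom, pos, derived_freq, uihs, ihs,
    neglog10_p, selected_allele, flag (empty string for cleanly scored
    rows).  ``bin_stats`` columns: bin_low, bin_high, n, mean_uihs,
    sd_uihs.
    """

    frame: pd.DataFrame
    bin_stats: pd.DataFrame = field(default_factory=pd.DataFrame)

    def scored(self) -> pd.DataFrame:
        return self.frame[self.frame["ihs"].notna()]


def unstandardized_ihs(
    panel: HaplotypePanel, core: int, ehh_floor: float = DEFAULT_EHH_FLOOR
) -> float:
    """uiHS = ln(iHH_ancestral / iHH_derived) at one core SNP.

    Raises ``ValueError`` when either integral is zero or an allele class
    has fewer than two carriers (the SNP is excluded from the scan with a
    reason rather than scored).
    """
    integ = integrated_ehh(panel, core, ehh_floor)
    if integ.ihh_ancestral <= 0.0 or integ.ihh_derived <= 0.0:
        raise ValueError(
            f"zero iHH at core {core} "
            f"(A={integ.ihh_ancestral:.3g}, D={integ.ihh_derived:.3g})"
        )
    return float(np.log(integ.ihh_ancestral / integ.ihh_derived))


def ihs_scan(
    panel: HaplotypePanel,
    maf_range: tuple[float, float] = DEFAULT_MAF_RANGE,
    ehh_floor: float = DEFAULT_EHH_FLOOR,
) -> pd.DataFrame:
    """Unstandardized iHS for every eligible SNP in a panel.

    Eligible cores have known polarity and derived frequency within
    ``maf_range``.  Ineligible or degenerate SNPs are retained as rows
    with NaN ``uihs`` and a reason in ``flag``.
    """
    dfreq = panel.derived_freq()
    rows = []
    for core in range(panel.n_sites):
        rec = {
            "snp_id": panel.snp_ids[core],
            "chrom": panel.chrom,
            "pos": int(panel.positions[core]),
            "derived_freq": float(dfreq[core]) if np.isfinite(dfreq[core]) else np.nan,
            "uihs": np.nan,
            "ihh_a": np.nan,
            "ihh_d": np.nan,
            "flag": "",
        }
        if panel.ancestral_is_ref[core] == ANC_UNKNOWN:
            rec["flag"] = "unknown_polarity"
        elif not (maf_range[0] <= dfreq[core] <= maf_range[1]):
            rec["flag"] = "freq_out_of_range"
        else:
            try:
                integ = integrated_ehh(panel, core, ehh_floor)
                if integ.ihh_ancestral <= 0.0 or integ.ihh_derived <= 0.0:
                    rec["flag"] = "zero_ihh"
                else:
                    rec["uihs"] = float(
                        np.log(integ.ihh_ancestral / integ.ihh_derived)
                    )
                    rec["ihh_a"] = integ.ihh_ancestral
                    rec["ihh_d"] = integ.ihh_derived
            except InsufficientCarriersError:
                rec["flag"] = "too_few_carriers"
        rows.append(rec)
    return pd.DataFrame(rows)


def _merge_bins(edges: np.ndarray, counts: np.ndarray, min_bin_n: int) -> np.ndarray:
    """Group contiguous frequency bins so each group reaches min_bin_n.

    Undersized bins are merged with their neighbor toward frequency 0.5.
    Returns, per original bin, the index of the group it belongs to.
    """
    groups = [[i] for i in range(len(counts))]
    gcounts = list(counts)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def center(g):
        return float(np.mean([centers[i] for i in groups[g]]))

    changed = True
    while changed and len(groups) > 1:
        changed = False
        for g in range(len(groups)):
            if gcounts[g] < min_bin_n:
                if g == len(groups) - 1:
                    tgt = g - 1
                elif g == 0:
                    tgt = 1
                else:
                    tgt = g + 1 if center(g) < 0.5 else g - 1
                keep, drop = min(g, tgt), max(g, tgt)
                groups[keep] = groups[keep] + groups[drop]
                gcounts[keep] += gcounts[drop]
                del groups[drop], gcounts[drop]
                changed = True
                break
    assign = np.empty(len(counts), dtype=np.int64)
    for g, members in enumerate(groups):
        for i in members:
            assign[i] = g
    return assign


def standardize(
    scores: pd.DataFrame,
    bin_width: float = DEFAULT_BIN_WIDTH,
    min_bin_n: int = DEFAULT_MIN_BIN_N,
    maf_range: tuple[float, float] = DEFAULT_MAF_RANGE,
) -> ScoreTable:
    """Standardize raw scores within derived-allele-frequency bins.

    ``scores`` needs columns ``uihs`` and ``derived_freq`` (extra columns
    pass through).  The frequency range is partitioned into contiguous
    ``bin_width`` bins; bins with fewer than ``min_bin_n`` scored SNPs are
    merged with the adjacent bin toward 0.5.  Within each (merged) bin,
    iHS = (uiHS - mean) / sd with the sample sd (ddof=1); a bin with zero
    variance leaves its SNPs flagged instead of scored.
    """
    frame = scores.copy()
    frame["ihs"] = np.nan
    if "flag" not in frame:
        frame["flag"] = ""
    ok = frame["uihs"].notna().to_numpy()
    edges = np.arange(maf_range[0], maf_range[1] + bin_width / 2, bin_width)
    if edges[-1] < maf_range[1]:
        edges = np.append(edges, maf_range[1])
    freq = frame.loc[ok, "derived_freq"].to_numpy()
    raw = frame.loc[ok, "uihs"].to_numpy()
    # right-inclusive last bin
    bin_idx = np.clip(np.searchsorted(edges, freq, side="right") - 1, 0, len(edges) - 2)
    counts = np.bincount(bin_idx, minlength=len(edges) - 1)
    assign = _merge_bins(edges, counts, min_bin_n)
    group = assign[bin_idx]

    std = np.full(raw.shape, np.nan)
    flags = np.array(frame.loc[ok, "flag"], dtype=object)
    stats = []
    for g in np.unique(assign):
        members = np.nonzero(assign == g)[0]
        sel = group == g
        n = int(sel.sum())
        low, high = float(edges[members.min()]), float(edges[members.max() + 1])
        mean = float(raw[sel].mean()) if n else np.nan
        sd = float(raw[sel].std(ddof=1)) if n >= 2 else np.nan
        stats.append(
            {"bin_low": low, "bin_high": high, "n": n, "mean_uihs": mean, "sd_uihs": sd}
        )
        if n >= 2 and sd and sd > 0:
            std[sel] = (raw[sel] - mean) / sd
        else:
            flags[sel] = "zero_variance_bin" if n >= 2 else "bin_too_small"
    frame.loc[ok, "ihs"] = std
    frame.loc[ok, "flag"] = flags
    frame["neglog10_p"] = score_to_neglog10p(frame["ihs"].to_numpy())
    if "ihh_a" in frame and "ihh_d" in frame:
        frame["selected_allele"] = np.where(
            frame["ihh_d"] > frame["ihh_a"], "derived", "ancestral"
        )
        frame.loc[frame["ihs"].isna(), "selected_allele"] = ""
    return ScoreTable(frame=frame, bin_stats=pd.DataFrame(stats))


def score_to_neglog10p(score) -> np.ndarray | float:
    """Two-sided Gaussian tail: -log10(2 * Phi(-|score|)).

    Strictly increasing in |score| and symmetric in sign; computed in log
    space so extreme scores keep full precision.
    """
    x = np.abs(np.asarray(score, dtype=float))
    out = -(np.log(2.0) + norm.logsf(x)) / np.log(10.0)
    if np.isscalar(score) or np.ndim(score) == 0:
        return float(out)
    return out


def significance_threshold(p_threshold: float = 1e-5) -> float:
    """|score| bound equivalent to a two-sided Gaussian p threshold."""
    return float(norm.isf(p_threshold / 2.0))


def significant_snps(
    table: ScoreTable | pd.DataFrame, p_threshold: float = 1e-5
) -> pd.DataFrame:
    """Rows whose two-sided Gaussian p is at or below the threshold."""
    frame = table.frame if isinstance(table, ScoreTable) else table
    bound = significance_threshold(p_threshold)
    return frame[frame["ihs"].abs() >= bound].copy()


def coincidence(
    tables: dict[str, ScoreTable | pd.DataFrame],
    p_threshold: float = 1e-5,
    min_pops: int = 2,
    locus_collapse_bp: int = 500,
) -> pd.DataFrame:
    """SNPs significant in at least ``min_pops`` populations.

    One row per shared SNP with per-population scores concatenated
    ("4.5; 4.6" style).  Shared SNPs within ``locus_collapse_bp`` of each
    other are annotated with a common ``locus_id`` (raw rows preserved).
    """
    hits = []
    for pop, table in tables.items():
        sig = significant_snps(table, p_threshold)
        for r in sig.itertuples():
            hits.append(
                {
                    "snp_id": r.snp_id, "chrom": r.chrom, "pos": r.pos,
                    "population": pop, "ihs": r.ihs,
                    "neglog10_p": r.neglog10_p,
                    "selected_allele": getattr(r, "selected_allele", ""),
                }
            )
    if not hits:
        return pd.DataFrame(
            columns=[
                "snp_id", "chrom", "pos", "n_populations", "populations",
                "abs_ihs", "neglog10_p", "selected_alleles", "locus_id",
            ]
        )
    df = pd.DataFrame(hits)
    rows = []
    for (snp, chrom, pos), grp in df.groupby(["snp_id", "chrom", "pos"], sort=False):
        if len(grp) < min_pops:
            continue
        grp = grp.sort_values("population")
        rows.append(
            {
                "snp_id": snp, "chrom": chrom, "pos": pos,
                "n_populations": len(grp),
                "populations": "; ".join(grp["population"]),
                "abs_ihs": "; ".join(f"{abs(v):.1f}" for v in grp["ihs"]),
                "neglog10_p": "; ".join(f"{v:.1f}" for v in grp["neglog10_p"]),
                "selected_alleles": "; ".join(grp["selected_allele"]),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out["locus_id"] = []
        return out
    out = out.sort_values(["chrom", "pos"]).reset_index(drop=True)
    locus, last_chrom, last_pos, lid = [], None, None, 0
    for r in out.itertuples():
        if last_chrom != r.chrom or r.pos - last_pos > locus_collapse_bp:
            lid += 1
        locus.append(lid)
        last_chrom, last_pos = r.chrom, r.pos
    out["locus_id"] = locus
    return out
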