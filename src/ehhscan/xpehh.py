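"""Cross-population XP-EHH scan.

XP-EHH contrasts the integrated pooled site-EHH (iES) at each SNP between
a test and a reference population: ln(iES_test / iES_ref), standardized
genome-wide to zero mean and unit sd.  Large positive values mark
haplotypes that stayed long in the test population after they had broken
down in the reference — the signature of a sweep in (or near fixation in)
the test population.  Significance calls keep only positive scores, since
negative ones point at the reference instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ehh import DEFAULT_EHH_FLOOR, InsufficientCarriersError, integrated_site_ehh
from .ihs import score_to_neglog10p, significance_threshold
from .panel import HaplotypePanel

__all__ = ["XPEHHResult", "xpehh_scan", "significant_xpehh", "pattern_matrix"]


@dataclass
class XPEHHResult:
    """Per-SNP XP-EHH table for one (test, reference) pair.

    ``frame`` columns: snp_id, chrom, pos, ln_ies_ratio, xpehh,
    neglog10_p, flag.
    """

    test_label: str
    reference_label: str
    frame: pd.DataFrame = field(default_factory=pd.DataFrame)


def _shared_polymorphic(
    panel_test: HaplotypePanel, panel_ref: HaplotypePanel
) -> tuple[np.ndarray, np.ndarray]:
    """Site indices, per panel, of shared positions polymorphic in the pool."""
    common, it, ir = np.intersect1d(
        panel_test.positions, panel_ref.positions, return_indices=True
    )
    if common.size == 0:
        return it, ir
    counts = (
        panel_test.haplotypes[:, it].sum(axis=0)
        + panel_ref.haplotypes[:, ir].sum(axis=0)
    )
    total = panel_test.n_haplotypes + panel_ref.n_haplotypes
    poly = (counts > 0) & (counts < total)
    return it[poly], ir[poly]


def xpehh_scan(
    panel_test: HaplotypePanel,
    panel_ref: HaplotypePanel,
    test_label: str = "test",
    reference_label: str = "ref",
    ehh_floor: float = DEFAULT_EHH_FLOOR,
) -> XPEHHResult:
    """XP-EHH over the sites shared by two panels.

    Sites monomorphic in the pooled pair are dropped; a SNP whose iES is
    zero on either side is excluded with a reason in ``flag``.  Scores are
    standardized against the genome-wide mean/sd of this pair.
    """
    if panel_test.chrom != panel_ref.chrom:
        raise ValueError("panels are on different chromosomes")
    it, ir = _shared_polymorphic(panel_test, panel_ref)
    rows = []
    for jt, jr in zip(it, ir):
        rec = {
            "snp_id": panel_test.snp_ids[jt],
            "chrom": panel_test.chrom,
            "pos": int(panel_test.positions[jt]),
            "ln_ies_ratio": np.nan,
            "flag": "",
        }
        try:
            ies_t, _ = integrated_site_ehh(panel_test, int(jt), ehh_floor)
            ies_r, _ = integrated_site_ehh(panel_ref, int(jr), ehh_floor)
            if ies_t <= 0.0 or ies_r <= 0.0:
                rec["flag"] = "zero_ies"
            else:
                rec["ln_ies_ratio"] = float(np.log(ies_t / ies_r))
        except InsufficientCarriersError:
            rec["flag"] = "undefined_site_ehh"
        rows.append(rec)
    frame = pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "pos", "ln_ies_ratio", "flag"],
    )
    ok = frame["ln_ies_ratio"].notna()
    vals = frame.loc[ok, "ln_ies_ratio"].to_numpy()
    frame["xpehh"] = np.nan
    if ok.sum() >= 2 and vals.std(ddof=1) > 0:
        frame.loc[ok, "xpehh"] = (vals - vals.mean()) / vals.std(ddof=1)
    frame["neglog10_p"] = score_to_neglog10p(frame["xpehh"].to_numpy())
    return XPEHHResult(
        test_label=test_label, reference_label=reference_label, frame=frame
    )


def significant_xpehh(
    result: XPEHHResult, p_threshold: float = 1e-5
) -> pd.DataFrame:
    """Significant rows: two-sided p at or below threshold AND score > 0.

    Only positive scores point at selection in the test (non-reference)
    population, so negative outliers are not reported.
    """
    bound = significance_threshold(p_threshold)
    f = result.frame
    return f[(f["xpehh"] > 0) & (f["xpehh"] >= bound)].copy()


def pattern_matrix(
    results: dict[tuple[str, str], XPEHHResult],
    p_threshold: float = 1e-5,
    locus_merge_bp: int = 100_000,
    reference_letters: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Locus-by-population grid of reference labels with significant signal.

    ``results`` is keyed by (population, reference).  Significant SNPs
    across all pairs are merged into loci (within ``locus_merge_bp`` on a
    chromosome); each grid cell lists the single-letter labels of the
    references under which that population shows a significant positive
    score at that locus, and an empty cell means no signal.  Locus rows
    are labeled by chromosome and the median hit position in Mb (one
    decimal).
    """
    refs = list(dict.fromkeys(ref for (_, ref) in results))
    letters = reference_letters or {r: r[0].upper() for r in refs}
    hits = []
    for (pop, ref), res in results.items():
        sig = significant_xpehh(res, p_threshold)
        for r in sig.itertuples():
            hits.append({"chrom": r.chrom, "pos": r.pos, "pop": pop, "ref": ref})
    pops = sorted({pop for (pop, _) in results})
    if not hits:
        return pd.DataFrame(columns=["chrom", "position_mb"] + pops)
    df = pd.DataFrame(hits).sort_values(["chrom", "pos"]).reset_index(drop=True)
    locus, last_chrom, last_pos, lid = [], None, None, -1
    for r in df.itertuples():
        if last_chrom != r.chrom or r.pos - last_pos > locus_merge_bp:
            lid += 1
        locus.append(lid)
        last_chrom, last_pos = r.chrom, r.pos
    df["locus"] = locus
    rows = []
    for lid, grp in df.groupby("locus"):
        row = {
            "chrom": grp["chrom"].iloc[0],
            "position_mb": round(float(np.median(grp["pos"])) / 1e6, 1),
        }
        for pop in pops:
            got = sorted(
                {letters[r] for r in grp.loc[grp["pop"] == pop, "ref"]},
                key=lambda x: [letters[r] for r in refs].index(x),
            )
            row[pop] = ", ".join(got)
        rows.append(row)
    return pd.DataFrame(rows, columns=["chrom", "position_mb"] + pops)
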