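"""Group-pooled allele-frequency over-representation scan.

Samples are pooled into population groups; at each site the derived-allele
frequency of a designated test group is compared with the maximum
frequency over all other groups.  A site is reported when the test
frequency exceeds a floor and the over-representation ratio reaches a
mode-specific multiple.  Significance comes from a Monte-Carlo null that
permutes sample-to-group labels (group sizes preserved): with k of N
permutations reaching the observed ratio anywhere in the tested locus,
p = (k + 1) / (N + 1), never exactly zero.

Three scan modes mirror increasingly strict uses of the same filter:

==========  =========  ==========  =================================
mode        freq floor ratio floor scope
==========  =========  ==========  =================================
locus       0.20       2.0         +/- 0.8 Mb around seed positions
genome      0.25       3.0         genome-wide, EHH-signal intersect
missense    0.20       1.8         protein-changing sites only
==========  =========  ==========  =================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .panel import PopulationMap, HaplotypePanel, merge_panels, ANC_ALT, ANC_UNKNOWN

__all__ = [
    "ScanConfig", "FreqScanResult", "dosage_table", "group_frequencies",
    "overrepresentation", "montecarlo_pvalue", "locus_scan", "genome_scan",
    "missense_scan", "haplotype_span",
]

MODE_DEFAULTS = {
    "locus": (0.20, 2.0),
    "genome": (0.25, 3.0),
    "missense": (0.20, 1.8),
}


@dataclass
class ScanConfig:
    """Configuration of one over-representation scan."""

    mode: str = "genome"
    maf_min: float | None = None
    ratio_min: float | None = None
    locus_window_bp: int = 800_000
    ehh_intersect_bp: int = 800_000
    locus_merge_bp: int = 500_000
    mc_iterations: int = 1000
    seed: int = 0
    denominator: str = "max"  # 'max' over other groups, or 'pooled' remainder

    def __post_init__(self) -> None:
        if self.mode not in MODE_DEFAULTS:
            raise ValueError(f"unknown mode {self.mode!r}; choose {sorted(MODE_DEFAULTS)}")
        d_maf, d_ratio = MODE_DEFAULTS[self.mode]
        if self.maf_min is None:
            self.maf_min = d_maf
        if self.ratio_min is None:
            self.ratio_min = d_ratio
        if self.denominator not in ("max", "pooled"):
            raise ValueError("denominator must be 'max' or 'pooled'")


@dataclass
class FreqScanResult:
    """Qualifying SNPs plus their locus-level summary."""

    snp_frame: pd.DataFrame
    locus_frame: pd.DataFrame = field(default_factory=pd.DataFrame)
    config: ScanConfig | None = None


def dosage_table(
    panels: dict[str, HaplotypePanel] | HaplotypePanel,
    pop_map: PopulationMap | None = None,
) -> pd.DataFrame:
    """Site-by-sample derived-allele dosage table from phased panels.

    Index is (chrom, pos); columns are sample ids.  Sites with unknown
    polarity use the non-reference allele, flagged in the ``unpolarized``
    attribute column set stored in ``DataFrame.attrs``.
    """
    panel = (
        panels if isinstance(panels, HaplotypePanel) else merge_panels(panels)
    )
    dos = panel.dosages().T.astype(np.int16)  # sites x samples
    flip = panel.ancestral_is_ref == ANC_ALT
    dos[flip] = 2 - dos[flip]
    df = pd.DataFrame(
        dos,
        index=pd.MultiIndex.from_arrays(
            [[panel.chrom] * panel.n_sites, panel.positions], names=["chrom", "pos"]
        ),
        columns=panel.sample_ids,
    )
    df.attrs["snp_ids"] = dict(zip(df.index, panel.snp_ids))
    df.attrs["unpolarized"] = set(
        df.index[np.asarray(panel.ancestral_is_ref) == ANC_UNKNOWN]
    )
    return df


def group_frequencies(
    dosages: pd.DataFrame, pop_map: PopulationMap
) -> pd.DataFrame:
    """Derived-allele frequency per group: allele count / (2 * group size).

    ``dosages`` holds diploid dosages in {0, 1, 2}, sites as rows and
    samples as columns.  Every sample must map to a group; empty groups
    are an error.
    """
    groups: dict[str, list[str]] = {}
    for s in dosages.columns:
        if s not in pop_map.sample_to_pop:
            raise ValueError(f"sample {s} has no population assignment")
        groups.setdefault(pop_map.group_of_sample(s), []).append(s)
    for g in pop_map.groups:
        if g not in groups:
            raise ValueError(f"group {g} has no samples in the dosage table")
    out = {}
    for g, samples in groups.items():
        out[g] = dosages[samples].sum(axis=1) / (2.0 * len(samples))
    return pd.DataFrame(out)


def _ratios(freqs: pd.DataFrame, test_group: str, denominator: str) -> pd.DataFrame:
    others = [c for c in freqs.columns if c != test_group]
    if not others:
        raise ValueError("need at least one non-test group")
    test = freqs[test_group].to_numpy(dtype=float)
    if denominator == "max":
        denom = freqs[others].to_numpy(dtype=float).max(axis=1)
    else:
        denom = freqs[others].to_numpy(dtype=float).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denom > 0, test / np.where(denom > 0, denom, 1.0), np.inf)
    ratio = np.where(test == 0, 0.0, ratio)
    return pd.DataFrame(
        {
            "test_freq": test,
            "max_other_freq": denom,
            "ratio": ratio,
            "infinite_ratio": (denom == 0) & (test > 0),
        },
        index=freqs.index,
    )


def overrepresentation(
    freqs: pd.DataFrame, test_group: str, cfg: ScanConfig
) -> pd.DataFrame:
    """Sites where the test group's frequency is both high and exceptional.

    Reported iff test frequency > ``maf_min`` and ratio >= ``ratio_min``;
    a zero denominator yields an infinite ratio that always passes, with a
    distinct flag.  Lowering either threshold only ever adds rows.
    """
    r = _ratios(freqs, test_group, cfg.denominator)
    # 1e-9 absolute slack absorbs float-division noise at exact multiples
    keep = (r["test_freq"] > cfg.maf_min) & (r["ratio"] >= cfg.ratio_min - 1e-9)
    out = r[keep].copy()
    out.insert(0, "test_group", test_group)
    return out


def _perm_stat(
    dos: np.ndarray,
    group_sizes: list[int],
    test_pos: int,
    maf_min: float,
    denominator: str,
) -> float:
    """Max over sites of the test-vs-others ratio for one label assignment."""
    # dos: sites x samples, columns already permuted; groups are contiguous
    bounds = np.cumsum([0] + group_sizes)
    freqs = np.empty((dos.shape[0], len(group_sizes)))
    for g in range(len(group_sizes)):
        freqs[:, g] = dos[:, bounds[g]:bounds[g + 1]].sum(axis=1) / (
            2.0 * group_sizes[g]
        )
    test = freqs[:, test_pos]
    others = np.delete(freqs, test_pos, axis=1)
    denom = others.max(axis=1) if denominator == "max" else others.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denom > 0, test / np.where(denom > 0, denom, 1.0), np.inf)
    ratio = np.where(test == 0, 0.0, ratio)
    ratio = np.where(test > maf_min, ratio, -np.inf)
    return float(ratio.max()) if ratio.size else -math.inf


def montecarlo_pvalue(
    dosages: pd.DataFrame,
    pop_map: PopulationMap,
    test_group: str,
    observed_ratio: float,
    cfg: ScanConfig,
    rng: np.random.Generator | None = None,
    tail_approx: bool = False,
):
    """Permutation p-value for an observed over-representation ratio.

    The null permutes sample-to-group labels with group sizes preserved;
    k counts permutations whose best qualifying ratio anywhere among the
    supplied sites reaches the observed one, and p = (k + 1) / (N + 1).
    With ``tail_approx`` a Gaussian approximation to the permutation tail
    is returned alongside (labeled; useful when the permutation floor
    1/(N+1) is hit).
    """
    if cfg.mc_iterations < 1:
        raise ValueError("mc_iterations must be >= 1")
    rng = rng or np.random.default_rng(cfg.seed)
    order = sorted(pop_map.groups)
    sizes = []
    cols = []
    for g in order:
        members = [s for s in dosages.columns if pop_map.group_of_sample(s) == g]
        if not members:
            raise ValueError(f"group {g} has no samples")
        sizes.append(len(members))
        cols.extend(members)
    dos = dosages[cols].to_numpy(dtype=np.int16)
    test_pos = order.index(test_group)
    n_samples = dos.shape[1]
    stats = np.empty(cfg.mc_iterations)
    for it in range(cfg.mc_iterations):
        perm = rng.permutation(n_samples)
        stats[it] = _perm_stat(
            dos[:, perm], sizes, test_pos, cfg.maf_min, cfg.denominator
        )
    k = int(np.sum(stats >= observed_ratio))
    p = (k + 1) / (cfg.mc_iterations + 1)
    if tail_approx:
        finite = stats[np.isfinite(stats)]
        if finite.size >= 2 and finite.std(ddof=1) > 0:
            z = (observed_ratio - finite.mean()) / finite.std(ddof=1)
            p_gauss = float(norm.sf(z))
        else:
            p_gauss = float("nan")
        return p, p_gauss
    return p


def haplotype_span(positions) -> tuple[int | None, int | None]:
    """(span_bp, span_kb) across a locus's SNPs: max - min position.

    kb is rounded to the nearest integer.  A single position has no span
    (returned as ``(None, None)`` and reported blank).
    """
    pos = [int(p) for p in positions]
    if len(pos) == 0:
        raise ValueError("no positions")
    if len(pos) == 1:
        return None, None
    span = max(pos) - min(pos)
    return span, round(span / 1000)


def _ratio_floor(ratios) -> float:
    """Report the locus's over-representation as a floor, one decimal down."""
    finite = [r for r in ratios if math.isfinite(r)]
    base = min(finite) if finite else math.inf
    return math.inf if math.isinf(base) else math.floor(base * 10) / 10


def _freq_context(
    dosages: pd.DataFrame, pop_map: PopulationMap
) -> pd.DataFrame:
    return group_frequencies(dosages, pop_map)


def locus_scan(
    dosages: pd.DataFrame,
    seed_loci: pd.DataFrame,
    pop_map: PopulationMap,
    cfg: ScanConfig | None = None,
    rng: np.random.Generator | None = None,
) -> FreqScanResult:
    """Over-representation scan restricted to windows around seed loci.

    ``seed_loci`` needs columns chrom, pos (one row per seed, e.g. the
    top SNPs of an iHS table).  Each seed is scanned within
    +/- ``locus_window_bp``; a window with no qualifying SNP yields a
    "Not found" row so every seed appears in the report.
    """
    cfg = cfg or ScanConfig(mode="locus")
    rng = rng or np.random.default_rng(cfg.seed)
    freqs = _freq_context(dosages, pop_map)
    chroms = dosages.index.get_level_values("chrom")
    positions = dosages.index.get_level_values("pos")
    test_groups = pop_map.test_groups or [pop_map.groups[0]]
    snp_rows, locus_rows = [], []
    for locus_no, seed in enumerate(seed_loci.itertuples(), start=1):
        in_win = (chroms == str(seed.chrom)) & (
            np.abs(positions - int(seed.pos)) <= cfg.locus_window_bp
        )
        best = None
        for tg in test_groups:
            hits = overrepresentation(freqs[np.asarray(in_win)], tg, cfg)
            if len(hits) and (best is None or hits["test_freq"].max() > best[1]["test_freq"].max()):
                best = (tg, hits)
        if best is None:
            locus_rows.append(
                {
                    "locus": locus_no, "seed_chrom": seed.chrom,
                    "seed_pos": int(seed.pos), "status": "Not found",
                    "n_snps": 0, "snp_ids": "", "max_freq": np.nan,
                    "max_freq_group": "", "ratio_floor": np.nan,
                    "mc_pvalue": np.nan,
                }
            )
            continue
        tg, hits = best
        win_dos = dosages[np.asarray(in_win)]
        p = montecarlo_pvalue(
            win_dos, pop_map, tg, float(hits["ratio"].replace(np.inf, np.nan).max()
                                        if np.isfinite(hits["ratio"]).any()
                                        else hits["ratio"].max()),
            cfg, rng=rng,
        )
        ids = [str(dosages.attrs.get("snp_ids", {}).get(i, f"{i[0]}:{i[1]}")) for i in hits.index]
        for (idx, r), sid in zip(hits.iterrows(), ids):
            snp_rows.append(
                {
                    "locus": locus_no, "snp_id": sid, "chrom": idx[0],
                    "pos": int(idx[1]), "test_group": r["test_group"],
                    "test_freq": r["test_freq"], "ratio": r["ratio"],
                }
            )
        locus_rows.append(
            {
                "locus": locus_no, "seed_chrom": seed.chrom,
                "seed_pos": int(seed.pos), "status": "found",
                "n_snps": len(hits), "snp_ids": ";".join(ids),
                "max_freq": float(hits["test_freq"].max()),
                "max_freq_group": tg,
                "ratio_floor": _ratio_floor(hits["ratio"]),
                "mc_pvalue": p,
            }
        )
    return FreqScanResult(
        snp_frame=pd.DataFrame(snp_rows),
        locus_frame=pd.DataFrame(locus_rows),
        config=cfg,
    )


def genome_scan(
    dosages: pd.DataFrame,
    ehh_signals: pd.DataFrame,
    pop_map: PopulationMap,
    cfg: ScanConfig | None = None,
    rng: np.random.Generator | None = None,
) -> FreqScanResult:
    """Genome-wide over-representation scan intersected with EHH signals.

    ``ehh_signals`` needs columns chrom, pos — the union of SNPs with
    strong iHS or significant XP-EHH in any scanned population.  A
    qualifying SNP survives only if such a signal lies within
    ``ehh_intersect_bp`` on the same chromosome.  Survivors are clustered
    into loci (within ``locus_merge_bp``) with haplotype spans and a
    Monte-Carlo p per locus.
    """
    cfg = cfg or ScanConfig(mode="genome")
    rng = rng or np.random.default_rng(cfg.seed)
    freqs = _freq_context(dosages, pop_map)
    test_groups = pop_map.test_groups or [pop_map.groups[0]]
    frames = []
    for tg in test_groups:
        hits = overrepresentation(freqs, tg, cfg)
        if len(hits):
            frames.append(hits)
    if frames:
        all_hits = pd.concat(frames).sort_index()
        # best test group per site
        all_hits = all_hits.loc[~all_hits.index.duplicated(keep="first")]
    else:
        all_hits = pd.DataFrame(
            columns=["test_group", "test_freq", "max_other_freq", "ratio", "infinite_ratio"]
        )

    sig_by_chrom: dict[str, np.ndarray] = {
        str(c): np.sort(g["pos"].to_numpy())
        for c, g in ehh_signals.groupby("chrom")
    } if len(ehh_signals) else {}

    def _supported(chrom: str, pos: int) -> bool:
        arr = sig_by_chrom.get(str(chrom))
        if arr is None or arr.size == 0:
            return False
        i = np.searchsorted(arr, pos)
        near = []
        if i < arr.size:
            near.append(arr[i] - pos)
        if i > 0:
            near.append(pos - arr[i - 1])
        return min(near) <= cfg.ehh_intersect_bp

    keep = [
        _supported(idx[0], int(idx[1])) for idx in all_hits.index
    ]
    survivors = all_hits[np.asarray(keep, dtype=bool)] if len(all_hits) else all_hits

    snp_rows, locus_rows = [], []
    if len(survivors):
        surv = survivors.reset_index()
        surv = surv.sort_values(["chrom", "pos"]).reset_index(drop=True)
        locus, last_chrom, last_pos, lid = [], None, None, 0
        for r in surv.itertuples():
            if last_chrom != r.chrom or r.pos - last_pos > cfg.locus_merge_bp:
                lid += 1
            locus.append(lid)
            last_chrom, last_pos = r.chrom, r.pos
        surv["locus"] = locus
        ids_map = dosages.attrs.get("snp_ids", {})
        for r in surv.itertuples():
            snp_rows.append(
                {
                    "locus": r.locus,
                    "snp_id": str(ids_map.get((r.chrom, r.pos), f"{r.chrom}:{r.pos}")),
                    "chrom": r.chrom, "pos": int(r.pos),
                    "test_group": r.test_group, "test_freq": r.test_freq,
                    "ratio": r.ratio,
                }
            )
        chroms = dosages.index.get_level_values("chrom")
        positions = dosages.index.get_level_values("pos")
        for lid, grp in surv.groupby("locus"):
            span_bp, span_kb = (
                haplotype_span(grp["pos"]) if len(grp) >= 2 else (None, None)
            )
            lo, hi = int(grp["pos"].min()), int(grp["pos"].max())
            tg = grp["test_group"].iloc[0]
            in_locus = (chroms == grp["chrom"].iloc[0]) & (
                (positions >= lo - cfg.locus_merge_bp)
                & (positions <= hi + cfg.locus_merge_bp)
            )
            finite = grp["ratio"][np.isfinite(grp["ratio"])]
            obs = float(finite.max()) if len(finite) else float("inf")
            p = montecarlo_pvalue(
                dosages[np.asarray(in_locus)], pop_map, tg, obs, cfg, rng=rng
            )
            locus_rows.append(
                {
                    "locus": lid, "chrom": grp["chrom"].iloc[0],
                    "first_pos": lo, "last_pos": hi,
                    "span_bp": span_bp if span_bp is not None else "",
                    "span_kb": span_kb if span_kb is not None else "",
                    "n_snps": len(grp),
                    "max_freq": float(grp["test_freq"].max()),
                    "max_freq_group": tg,
                    "ratio_floor": _ratio_floor(grp["ratio"]),
                    "mc_pvalue": p,
                }
            )
    return FreqScanResult(
        snp_frame=pd.DataFrame(snp_rows),
        locus_frame=pd.DataFrame(locus_rows),
        config=cfg,
    )


def missense_scan(
    dosages: pd.DataFrame,
    consequences: pd.DataFrame,
    pop_map: PopulationMap,
    cfg: ScanConfig | None = None,
) -> FreqScanResult:
    """Over-representation scan restricted to missense sites.

    ``consequences`` needs columns chrom, pos, effect (and optionally
    gene); only rows with effect == 'missense' are scanned.  The report
    lists each qualifying SNP with the test group(s) in which it
    qualifies ('A+B' when several do).
    """
    cfg = cfg or ScanConfig(mode="missense")
    mis = consequences[consequences["effect"] == "missense"]
    mis_keys = {(str(r.chrom), int(r.pos)) for r in mis.itertuples()}
    gene_map = {
        (str(r.chrom), int(r.pos)): getattr(r, "gene", "")
        for r in mis.itertuples()
    }
    keep = [
        (str(c), int(p)) in mis_keys
        for c, p in zip(
            dosages.index.get_level_values("chrom"),
            dosages.index.get_level_values("pos"),
        )
    ]
    sub = dosages[np.asarray(keep, dtype=bool)]
    freqs = _freq_context(sub, pop_map) if len(sub) else pd.DataFrame()
    test_groups = pop_map.test_groups or [pop_map.groups[0]]
    per_site: dict[tuple, dict] = {}
    if len(sub):
        for tg in test_groups:
            hits = overrepresentation(freqs, tg, cfg)
            for idx, r in hits.iterrows():
                rec = per_site.setdefault(
                    idx, {"groups": [], "test_freq": 0.0, "ratio": 0.0}
                )
                rec["groups"].append(tg)
                if r["test_freq"] > rec["test_freq"]:
                    rec["test_freq"] = float(r["test_freq"])
                    rec["ratio"] = float(r["ratio"])
    ids_map = dosages.attrs.get("snp_ids", {})
    rows = []
    for idx in sorted(per_site, key=lambda k: (str(k[0]), int(k[1]))):
        rec = per_site[idx]
        rows.append(
            {
                "snp_id": str(ids_map.get(idx, f"{idx[0]}:{idx[1]}")),
                "chrom": idx[0], "pos": int(idx[1]),
                "gene": gene_map.get((str(idx[0]), int(idx[1])), ""),
                "test_freq": rec["test_freq"],
                "ratio_floor": _ratio_floor([rec["ratio"]]),
                "test_groups": "+".join(rec["groups"]),
            }
        )
    return FreqScanResult(snp_frame=pd.DataFrame(rows), config=cfg)
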