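"""Phased haplotype panels: VCF input/output, polarization, QC and masking.

A :class:`HaplotypePanel` holds one chromosome's worth of phased biallelic
genotypes as a 0/1 matrix with two adjacent rows per sample.  Ancestral
state per site is tracked as a three-way code (REF ancestral, ALT
ancestral, unknown) so that derived-allele statistics are only ever taken
at sites whose polarity is resolved.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hwe import hwe_exact_p

log = logging.getLogger(__name__)

# ancestral_is_ref codes
ANC_REF = 1
ANC_ALT = 0
ANC_UNKNOWN = -1

_SNP_ALLELES = frozenset("ACGT")


class PhasingError(ValueError):
    """An unphased genotype was found where phased haplotypes are required."""


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes for one chromosome.

    ``haplotypes`` has shape ``(2 * n_samples, n_sites)`` with entries in
    {0, 1} (0 = REF, 1 = ALT); rows ``2i`` and ``2i + 1`` are the two
    haplotypes of ``sample_ids[i]``.  ``ancestral_is_ref`` is an int8 code
    per site: 1 if REF is ancestral, 0 if ALT is ancestral, -1 if unknown.
    ``missing`` optionally marks entries whose genotype call was missing in
    the source; panels that have passed QC carry no missing entries.
    """

    chrom: str
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    haplotypes: np.ndarray
    sample_ids: list[str]
    ancestral_is_ref: np.ndarray
    snp_ids: np.ndarray | None = None
    missing: np.ndarray | None = None
    load_report: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.ancestral_is_ref = np.asarray(self.ancestral_is_ref, dtype=np.int8)
        if self.snp_ids is None:
            self.snp_ids = np.array(
                [f"{self.chrom}:{p}" for p in self.positions], dtype=object
            )
        else:
            self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        n_hap, n_sites = self.haplotypes.shape
        if n_hap % 2 != 0:
            raise ValueError("haplotype row count must be even (two per sample)")
        if n_hap != 2 * len(self.sample_ids):
            raise ValueError("haplotype rows do not match sample_ids")
        for arr, name in [
            (self.positions, "positions"), (self.ref, "ref"), (self.alt, "alt"),
            (self.ancestral_is_ref, "ancestral_is_ref"), (self.snp_ids, "snp_ids"),
        ]:
            if len(arr) != n_sites:
                raise ValueError(f"{name} length does not match site count")
        if n_sites and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise ValueError("haplotype entries must be 0 or 1")
        self._derived_cache = None  # lazy derived-coded matrix (not a field)

    # -- basic shape --------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    # -- allele bookkeeping -------------------------------------------
    def alt_freq(self) -> np.ndarray:
        """ALT allele frequency per site (missing entries excluded)."""
        if self.missing is None:
            return self.haplotypes.mean(axis=0)
        ok = ~self.missing
        with np.errstate(invalid="ignore"):
            return np.where(
                ok.sum(axis=0) > 0,
                (self.haplotypes * ok).sum(axis=0) / np.maximum(ok.sum(axis=0), 1),
                np.nan,
            )

    def derived_freq(self) -> np.ndarray:
        """Derived-allele frequency per site; NaN where polarity is unknown."""
        af = self.alt_freq()
        out = np.where(self.ancestral_is_ref == ANC_REF, af, 1.0 - af)
        return np.where(self.ancestral_is_ref == ANC_UNKNOWN, np.nan, out)

    def derived_haplotypes(self) -> np.ndarray:
        """Haplotype matrix recoded so 1 = derived allele.

        Sites with unknown polarity keep the ALT coding (they may serve as
        extension markers, where only identity matters, but never as cores).
        """
        if self._derived_cache is None:
            flip = (self.ancestral_is_ref == ANC_ALT).astype(np.uint8)
            self._derived_cache = np.ascontiguousarray(
                self.haplotypes ^ flip[np.newaxis, :]
            )
        return self._derived_cache

    def dosages(self) -> np.ndarray:
        """Diploid ALT dosages, shape (n_samples, n_sites)."""
        return (
            self.haplotypes[0::2].astype(np.int16) + self.haplotypes[1::2]
        )

    # -- subsetting ----------------------------------------------------
    def take_sites(self, idx) -> "HaplotypePanel":
        idx = np.asarray(idx)
        return replace(
            self,
            positions=self.positions[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            haplotypes=self.haplotypes[:, idx],
            ancestral_is_ref=self.ancestral_is_ref[idx],
            snp_ids=self.snp_ids[idx],
            missing=None if self.missing is None else self.missing[:, idx],
        )

    def take_samples(self, idx) -> "HaplotypePanel":
        idx = np.asarray(idx)
        rows = np.empty(2 * idx.size, dtype=np.int64)
        rows[0::2] = 2 * idx
        rows[1::2] = 2 * idx + 1
        return replace(
            self,
            haplotypes=self.haplotypes[rows],
            sample_ids=[self.sample_ids[i] for i in idx],
            missing=None if self.missing is None else self.missing[rows],
        )

    def site_index(self, pos: int) -> int:
        i = int(np.searchsorted(self.positions, pos))
        if i >= self.n_sites or self.positions[i] != pos:
            raise KeyError(f"no site at {self.chrom}:{pos}")
        return i


@dataclass
class PopulationMap:
    """Sample-to-population and population-to-group assignments."""

    sample_to_pop: dict[str, str]
    pop_to_group: dict[str, str] = field(default_factory=dict)
    test_groups: list[str] = field(default_factory=list)
    reference_populations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for pop in set(self.sample_to_pop.values()):
            self.pop_to_group.setdefault(pop, pop)
        bad = set(self.test_groups) & {
            self.pop_to_group[p] for p in self.reference_populations
        }
        if bad:
            raise ValueError(f"test groups overlap the reference set: {sorted(bad)}")

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.sample_to_pop.values()))

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.pop_to_group.values()))

    def group_of_sample(self, sample: str) -> str:
        return self.pop_to_group[self.sample_to_pop[sample]]

    def samples_in_pop(self, pop: str) -> list[str]:
        return [s for s, p in self.sample_to_pop.items() if p == pop]

    def sample_indices(self, panel: HaplotypePanel, pop: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(panel.sample_ids) if self.sample_to_pop.get(s) == pop],
            dtype=np.int64,
        )

    def validate_panel(self, panel: HaplotypePanel) -> None:
        unmapped = [s for s in panel.sample_ids if s not in self.sample_to_pop]
        if unmapped:
            raise ValueError(f"samples without population assignment: {unmapped[:5]}")


@dataclass
class ChromExtent:
    """Physical extent of a chromosome, with an optional centromere interval."""

    start: int
    end: int
    centromere: tuple[int, int] | None = None


@dataclass
class QCThresholds:
    """Quality-control thresholds applied before the scans.

    Defaults follow standard array-QC practice: samples with call rate
    below 0.95 excluded, then SNPs with missing rate above 0.05, minor
    allele frequency below 0.01 or exact-HWE p below 1e-5 dropped, and
    200 kb masks applied at chromosome ends and around centromeres.
    """

    sample_call_rate_min: float = 0.95
    snp_missing_max: float = 0.05
    maf_min: float = 0.01
    hwe_p_min: float = 1e-5
    relatedness_exclusions: list[str] = field(default_factory=list)
    end_mask_bp: int = 200_000
    extra_masks: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("sample_call_rate_min", "snp_missing_max", "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.hwe_p_min <= 1.0:
            raise ValueError("hwe_p_min must be a probability")
        if self.end_mask_bp < 0:
            raise ValueError("end_mask_bp must be non-negative")


@dataclass
class QCReport:
    """Counts removed per criterion, in application order."""

    steps: list[tuple[str, int, list[str]]] = field(default_factory=list)

    def add(self, criterion: str, removed_ids: list) -> None:
        self.steps.append((criterion, len(removed_ids), [str(x) for x in removed_ids]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"criterion": c, "n_removed": n, "removed": ";".join(ids[:50])}
                for c, n, ids in self.steps
            ]
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF input / output
# ---------------------------------------------------------------------------

def load_phased_vcf(path, region: tuple[str, int, int] | None = None) -> HaplotypePanel:
    """Read a phased multi-sample VCF into a :class:`HaplotypePanel`.

    Only biallelic SNP records are retained; multiallelic or non-SNP
    records are skipped with a tally in ``panel.load_report``, as are
    duplicate positions and zero-coordinate records.  An unphased genotype
    raises :class:`PhasingError` naming the record.  Missing genotypes are
    kept as 0 with the ``missing`` mask set.  If an ``AA`` INFO tag is
    present, the panel is polarized from it on load.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    tally = {"non_snp": 0, "multiallelic": 0, "duplicate": 0, "zero_coordinate": 0}
    chroms: set[str] = set()
    positions, refs, alts, ids, anc, cols, miss_cols = [], [], [], [], [], [], []
    seen: set[tuple[str, int]] = set()
    for v in vcf:
        if region is not None:
            rchrom, rstart, rend = region
            if v.CHROM != rchrom or not (rstart <= v.POS <= rend):
                continue
        if v.POS == 0:
            tally["zero_coordinate"] += 1
            continue
        if len(v.ALT) != 1:
            tally["multiallelic"] += 1
            continue
        if v.REF not in _SNP_ALLELES or v.ALT[0] not in _SNP_ALLELES:
            tally["non_snp"] += 1
            continue
        key = (v.CHROM, v.POS)
        if key in seen:
            tally["duplicate"] += 1
            continue
        seen.add(key)
        gts = v.genotype.array()  # (n_samples, 3): allele0, allele1, phased
        missing = gts[:, :2] < 0
        if np.any((gts[:, 2] == 0) & ~missing.any(axis=1)):
            bad = samples[int(np.nonzero((gts[:, 2] == 0) & ~missing.any(axis=1))[0][0])]
            raise PhasingError(
                f"unphased genotype at {v.CHROM}:{v.POS} (sample {bad})"
            )
        col = np.clip(gts[:, :2], 0, 1).astype(np.uint8).reshape(-1)
        chroms.add(v.CHROM)
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        aa = v.INFO.get("AA")
        if aa is None:
            anc.append(ANC_UNKNOWN)
        elif aa.upper() == v.REF:
            anc.append(ANC_REF)
        elif aa.upper() == v.ALT[0]:
            anc.append(ANC_ALT)
        else:
            anc.append(ANC_UNKNOWN)
        cols.append(col)
        miss_cols.append(missing.reshape(-1))
    vcf.close()
    if len(chroms) > 1:
        raise ValueError(
            f"panel must be single-chromosome; found {sorted(chroms)} "
            "(pass region=... to select one)"
        )
    chrom = chroms.pop() if chroms else (region[0] if region else "")
    n_sites = len(positions)
    haps = (
        np.stack(cols, axis=1)
        if n_sites
        else np.zeros((2 * len(samples), 0), dtype=np.uint8)
    )
    miss = (
        np.stack(miss_cols, axis=1)
        if n_sites
        else np.zeros((2 * len(samples), 0), dtype=bool)
    )
    order = np.argsort(np.asarray(positions, dtype=np.int64), kind="stable") if n_sites else []
    panel = HaplotypePanel(
        chrom=chrom,
        positions=np.asarray(positions, dtype=np.int64)[order] if n_sites else [],
        ref=np.asarray(refs, dtype=object)[order] if n_sites else [],
        alt=np.asarray(alts, dtype=object)[order] if n_sites else [],
        haplotypes=haps[:, order] if n_sites else haps,
        sample_ids=samples,
        ancestral_is_ref=np.asarray(anc, dtype=np.int8)[order] if n_sites else [],
        snp_ids=np.asarray(ids, dtype=object)[order] if n_sites else None,
        missing=miss[:, order] if (n_sites and miss.any()) else None,
    )
    panel.load_report = {**tally, "n_sites": panel.n_sites, "n_samples": panel.n_samples}
    skipped = {k: v for k, v in tally.items() if v}
    if skipped:
        log.warning("load_phased_vcf skipped records: %s", skipped)
    return panel


def write_phased_vcf(panel: HaplotypePanel, path) -> None:
    """Write a panel as an uncompressed phased VCF 4.2 file.

    Ancestral states are emitted through the ``AA`` INFO tag for sites with
    known polarity, so a write/read round trip preserves polarization.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        haps = panel.haplotypes
        miss = panel.missing
        for j in range(panel.n_sites):
            if panel.ancestral_is_ref[j] == ANC_REF:
                info = f"AA={panel.ref[j]}"
            elif panel.ancestral_is_ref[j] == ANC_ALT:
                info = f"AA={panel.alt[j]}"
            else:
                info = "."
            gts = []
            for i in range(panel.n_samples):
                a, b = haps[2 * i, j], haps[2 * i + 1, j]
                if miss is not None and (miss[2 * i, j] or miss[2 * i + 1, j]):
                    gts.append(".|.")
                else:
                    gts.append(f"{a}|{b}")
            fh.write(
                f"{panel.chrom}\t{panel.positions[j]}\t{panel.snp_ids[j]}\t"
                f"{panel.ref[j]}\t{panel.alt[j]}\t.\tPASS\t{info}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# TSV / BED side inputs
# ---------------------------------------------------------------------------

def read_ancestral_tsv(path) -> dict[tuple[str, int], str]:
    """Read a ``chrom<TAB>pos<TAB>ancestral_allele`` map."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "pos", "allele"],
        dtype={"chrom": str, "pos": np.int64, "allele": str}, comment="#",
    )
    return {(r.chrom, int(r.pos)): r.allele.upper() for r in df.itertuples()}


def read_population_map(
    path,
    test_groups: list[str] | None = None,
    reference_populations: list[str] | None = None,
) -> PopulationMap:
    """Read a ``sample<TAB>population<TAB>group`` map."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["sample", "pop", "group"],
        dtype=str, comment="#",
    )
    pop_to_group: dict[str, str] = {}
    for r in df.itertuples():
        prev = pop_to_group.setdefault(r.pop, r.group)
        if prev != r.group:
            raise ValueError(f"population {r.pop} mapped to two groups")
    dup = df["sample"][df["sample"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample rows: {sorted(set(dup))[:5]}")
    return PopulationMap(
        sample_to_pop=dict(zip(df["sample"], df["pop"])),
        pop_to_group=pop_to_group,
        test_groups=test_groups or [],
        reference_populations=reference_populations or [],
    )


def write_population_map(pop_map: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        for s, p in pop_map.sample_to_pop.items():
            fh.write(f"{s}\t{p}\t{pop_map.pop_to_group[p]}\n")


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read BED intervals, converted to 1-based closed coordinates."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]) + 1, int(parts[2])))
    return out


# ---------------------------------------------------------------------------
# Polarization, QC, masking
# ---------------------------------------------------------------------------

def polarize(
    panel: HaplotypePanel, ancestral: dict[tuple[str, int], str]
) -> HaplotypePanel:
    """Assign ancestral/derived polarity from an outgroup allele map.

    Sites whose stated ancestral allele matches neither REF nor ALT — or
    that are absent from the map — are marked unknown and excluded from
    polarity-dependent statistics downstream.
    """
    if not ancestral:
        warnings.warn("empty ancestral map: all sites marked unknown")
    codes = np.full(panel.n_sites, ANC_UNKNOWN, dtype=np.int8)
    for j in range(panel.n_sites):
        a = ancestral.get((panel.chrom, int(panel.positions[j])))
        if a is None:
            continue
        a = a.upper()
        if a == panel.ref[j]:
            codes[j] = ANC_REF
        elif a == panel.alt[j]:
            codes[j] = ANC_ALT
    return replace(panel, ancestral_is_ref=codes)


def qc_filter(
    panel: HaplotypePanel,
    thresholds: QCThresholds | None = None,
    missing: np.ndarray | None = None,
    pop_map: PopulationMap | None = None,
) -> tuple[HaplotypePanel, QCReport]:
    """Apply sample- then site-level QC filters.

    Order of application: relatedness exclusion list, sample call rate,
    SNP missing rate, minor allele frequency, exact HWE (per population
    when ``pop_map`` is given, pooled otherwise; a site fails if any
    population fails).  Any site retaining missing entries after those
    filters is dropped, so the returned panel is complete — the EHH
    statistics downstream assume complete haplotypes and nothing here
    imputes.
    """
    thresholds = thresholds or QCThresholds()
    report = QCReport()
    if missing is None:
        missing = panel.missing
    if missing is None:
        missing = np.zeros_like(panel.haplotypes, dtype=bool)
    missing = np.asarray(missing, dtype=bool)
    if missing.shape != panel.haplotypes.shape:
        raise ValueError("missingness mask shape does not match panel")

    # 1. explicit relatedness exclusions
    excl = set(thresholds.relatedness_exclusions)
    keep = np.array([s not in excl for s in panel.sample_ids])
    report.add("relatedness_exclusion", [s for s in panel.sample_ids if s in excl])
    panel2 = panel.take_samples(np.nonzero(keep)[0])
    missing = missing[np.repeat(keep, 2)]

    # 2. sample call rate (genotype-level: a genotype is missing if either
    # haplotype entry is masked)
    geno_miss = missing[0::2] | missing[1::2]
    call_rate = (
        1.0 - geno_miss.mean(axis=1) if panel2.n_sites else np.ones(panel2.n_samples)
    )
    keep_s = call_rate >= thresholds.sample_call_rate_min
    report.add(
        "sample_call_rate",
        [s for s, k in zip(panel2.sample_ids, keep_s) if not k],
    )
    panel2 = panel2.take_samples(np.nonzero(keep_s)[0])
    missing = missing[np.repeat(keep_s, 2)]
    if panel2.n_samples == 0:
        raise ValueError("all samples removed by QC")
    geno_miss = missing[0::2] | missing[1::2]

    # 3. SNP missing rate
    snp_miss = geno_miss.mean(axis=0)
    keep_v = snp_miss <= thresholds.snp_missing_max
    report.add("snp_missing_rate", list(panel2.snp_ids[~keep_v]))
    panel2 = panel2.take_sites(np.nonzero(keep_v)[0])
    missing = missing[:, keep_v]
    geno_miss = geno_miss[:, keep_v]

    # 4. minor allele frequency (over non-missing alleles)
    ok = ~missing
    denom = np.maximum(ok.sum(axis=0), 1)
    af = (panel2.haplotypes * ok).sum(axis=0) / denom
    maf = np.minimum(af, 1.0 - af)
    keep_v = maf >= thresholds.maf_min
    report.add("maf", list(panel2.snp_ids[~keep_v]))
    panel2 = panel2.take_sites(np.nonzero(keep_v)[0])
    missing = missing[:, keep_v]
    geno_miss = geno_miss[:, keep_v]

    # 5. exact HWE
    def _hwe_fail(sub: np.ndarray, sub_miss: np.ndarray) -> np.ndarray:
        dos = sub[0::2].astype(np.int16) + sub[1::2]
        gm = sub_miss[0::2] | sub_miss[1::2]
        fails = np.zeros(sub.shape[1], dtype=bool)
        for j in range(sub.shape[1]):
            d = dos[~gm[:, j], j]
            n_aa = int(np.sum(d == 0))
            n_het = int(np.sum(d == 1))
            n_bb = int(np.sum(d == 2))
            fails[j] = hwe_exact_p(n_aa, n_het, n_bb) < thresholds.hwe_p_min
        return fails

    if pop_map is not None:
        fail = np.zeros(panel2.n_sites, dtype=bool)
        for pop in sorted({pop_map.sample_to_pop.get(s) for s in panel2.sample_ids} - {None}):
            idx = pop_map.sample_indices(panel2, pop)
            rows = np.empty(2 * idx.size, dtype=np.int64)
            rows[0::2], rows[1::2] = 2 * idx, 2 * idx + 1
            fail |= _hwe_fail(panel2.haplotypes[rows], missing[rows])
    else:
        fail = _hwe_fail(panel2.haplotypes, missing)
    report.add("hwe", list(panel2.snp_ids[fail]))
    panel2 = panel2.take_sites(np.nonzero(~fail)[0])
    missing = missing[:, ~fail]

    # 6. residual missing entries (no imputation: complete panels only)
    resid = missing.any(axis=0)
    report.add("residual_missing", list(panel2.snp_ids[resid]))
    panel2 = panel2.take_sites(np.nonzero(~resid)[0])
    panel2 = replace(panel2, missing=None)
    return panel2, report


def apply_masks(
    panel: HaplotypePanel,
    chrom_extents: dict[str, ChromExtent],
    thresholds: QCThresholds | None = None,
) -> HaplotypePanel:
    """Drop sites near chromosome ends/centromeres or inside extra masks.

    A site is removed when its distance to a chromosome boundary (or to
    the centromere interval) is strictly less than ``end_mask_bp``, or
    when it lies inside any interval of ``extra_masks`` (1-based closed).
    """
    thresholds = thresholds or QCThresholds()
    ext = chrom_extents.get(panel.chrom)
    pos = panel.positions
    remove = np.zeros(panel.n_sites, dtype=bool)
    if ext is not None and thresholds.end_mask_bp > 0:
        m = thresholds.end_mask_bp
        remove |= (pos - ext.start) < m
        remove |= (ext.end - pos) < m
        if ext.centromere is not None:
            cs, ce = ext.centromere
            remove |= ((cs - pos) < m) & ((pos - ce) < m)
    for chrom, s, e in thresholds.extra_masks:
        if chrom == panel.chrom:
            remove |= (pos >= s) & (pos <= e)
    return panel.take_sites(np.nonzero(~remove)[0])


def merge_panels(
    panels: dict[str, HaplotypePanel], order: list[str] | None = None
) -> HaplotypePanel:
    """Horizontally merge per-population panels sharing one site grid."""
    order = order or sorted(panels)
    first = panels[order[0]]
    for name in order[1:]:
        p = panels[name]
        if (
            p.chrom != first.chrom
            or p.n_sites != first.n_sites
            or np.any(p.positions != first.positions)
        ):
            raise ValueError("panels must share chromosome and site grid to merge")
    return replace(
        first,
        haplotypes=np.vstack([panels[n].haplotypes for n in order]),
        sample_ids=[s for n in order for s in panels[n].sample_ids],
        missing=None,
    )
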