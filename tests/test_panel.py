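"""Panel IO, polarization, QC filtering and masking."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest

from ehhscan import (
    ChromExtent,
    PhasingError,
    QCThresholds,
    apply_masks,
    hwe_exact_p,
    load_phased_vcf,
    polarize,
    qc_filter,
    write_phased_vcf,
    read_bed,
)
from ehhscan.panel import ANC_ALT, ANC_REF, ANC_UNKNOWN

from conftest import build_panel, random_panel


# ---------------------------------------------------------------------------
# VCF input/output
# ---------------------------------------------------------------------------

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1>\n"
    '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsA\tsB\n"
)


def _write_vcf(tmp_path, body, name="t.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + body)
    return path


def test_load_parses_phased_biallelic_records(tmp_path):
    path = _write_vcf(
        tmp_path,
        "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\n"
        "1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0|0\t0|1\n"
        "1\t300\trs3\tA\tC\t.\tPASS\t.\tGT\t1|0\t0|0\n",
    )
    panel = load_phased_vcf(path)
    assert panel.haplotypes.shape == (4, 3)
    assert list(panel.positions) == [100, 200, 300]
    assert panel.haplotypes[:, 0].tolist() == [0, 1, 1, 1]


def test_load_rejects_unphased_genotype(tmp_path):
    path = _write_vcf(
        tmp_path, "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\t1|1\n"
    )
    with pytest.raises(PhasingError, match="1:100"):
        load_phased_vcf(path)


def test_load_skips_non_snp_and_duplicates_with_tally(tmp_path):
    path = _write_vcf(
        tmp_path,
        "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\n"
        "1\t150\tindel\tAT\tA\t.\tPASS\t.\tGT\t0|1\t1|1\n"
        "1\t100\tdup\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\n"
        "1\t0\tzero\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\n",
    )
    panel = load_phased_vcf(path)
    assert panel.n_sites == 1
    assert panel.load_report["non_snp"] == 1
    assert panel.load_report["duplicate"] == 1
    assert panel.load_report["zero_coordinate"] == 1


def test_write_read_round_trip_preserves_everything(tmp_path):
    rng = np.random.default_rng(7)
    panel = random_panel(rng, n_hap=6, n_sites=12)
    panel.ancestral_is_ref[3] = ANC_ALT
    panel.ancestral_is_ref[4] = ANC_UNKNOWN
    path = tmp_path / "rt.vcf"
    write_phased_vcf(panel, path)
    back = load_phased_vcf(path)
    assert np.array_equal(back.haplotypes, panel.haplotypes)
    assert np.array_equal(back.positions, panel.positions)
    assert list(back.ref) == list(panel.ref)
    assert list(back.alt) == list(panel.alt)
    assert np.array_equal(back.ancestral_is_ref, panel.ancestral_is_ref)


# ---------------------------------------------------------------------------
# Polarization
# ---------------------------------------------------------------------------

def test_polarize_assigns_codes_and_flags_mismatches():
    panel = build_panel(
        np.zeros((4, 3), dtype=np.uint8),
        positions=[10, 20, 30],
        ref=["A", "A", "A"],
        alt=["G", "G", "G"],
        ancestral_is_ref=[ANC_UNKNOWN] * 3,
    )
    out = polarize(panel, {("1", 10): "A", ("1", 20): "G", ("1", 30): "C"})
    assert out.ancestral_is_ref.tolist() == [ANC_REF, ANC_ALT, ANC_UNKNOWN]


def test_polarize_empty_map_warns_all_unknown():
    panel = build_panel(np.zeros((4, 2), dtype=np.uint8))
    with pytest.warns(UserWarning):
        out = polarize(panel, {})
    assert (out.ancestral_is_ref == ANC_UNKNOWN).all()


def test_polarize_partial_map_counts_by_construction():
    rng = np.random.default_rng(3)
    panel = random_panel(rng, n_hap=4, n_sites=10)
    anc = {}
    for j in range(7):
        anc[("1", int(panel.positions[j]))] = panel.ref[j]
    # 3 sites absent from the map -> unknown
    out = polarize(panel, anc)
    assert int((out.ancestral_is_ref != ANC_UNKNOWN).sum()) == 7
    assert int((out.ancestral_is_ref == ANC_UNKNOWN).sum()) == 3


# ---------------------------------------------------------------------------
# Exact HWE
# ---------------------------------------------------------------------------

def hwe_oracle(n_aa, n_ab, n_bb):
    """Exact-fraction enumeration over heterozygote counts (independent path)."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    probs = {}
    for het in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
        aa = (n_a - het) // 2
        bb = n - het - aa
        if bb < 0:
            continue
        p = (
            Fraction(math.factorial(n), math.factorial(aa) * math.factorial(het) * math.factorial(bb))
            * Fraction(2) ** het
            * Fraction(
                math.factorial(n_a) * math.factorial(2 * n - n_a),
                math.factorial(2 * n),
            )
        )
        probs[het] = p
    p_obs = probs[n_ab]
    return float(sum(p for p in probs.values() if p <= p_obs))


@pytest.mark.parametrize(
    "counts",
    [(25, 50, 25), (50, 0, 50), (10, 5, 3), (3, 17, 40), (1, 1, 1), (0, 5, 95)],
)
def test_hwe_exact_matches_enumeration_oracle(counts):
    assert hwe_exact_p(*counts) == pytest.approx(hwe_oracle(*counts), rel=1e-10)


def test_hwe_extremes():
    # maximal disequilibrium: no heterozygotes at 50/50 alleles
    assert hwe_exact_p(50, 0, 50) < 1e-5
    # perfect proportions retained at any sane threshold
    assert hwe_exact_p(25, 50, 25) > 1e-5
    # monomorphic -> no evidence
    assert hwe_exact_p(100, 0, 0) == 1.0


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

def _qc_panel_with_missing(rng, n_samples=20, n_sites=40):
    haps = rng.integers(0, 2, size=(2 * n_samples, n_sites)).astype(np.uint8)
    # keep all sites comfortably polymorphic
    haps[: n_samples, :] = 0
    haps[n_samples:, :] = 1
    haps = rng.permuted(haps, axis=0)
    return build_panel(haps)


def test_sample_below_call_rate_dropped_first():
    rng = np.random.default_rng(11)
    panel = _qc_panel_with_missing(rng)
    missing = np.zeros_like(panel.haplotypes, dtype=bool)
    # sample 0 missing 10% of genotypes
    missing[0, :4] = missing[1, :4] = True
    filtered, report = qc_filter(panel, QCThresholds(), missing=missing)
    assert filtered.n_samples == panel.n_samples - 1
    steps = dict((c, ids) for c, _, ids in report.steps)
    assert steps["sample_call_rate"] == ["s0"]


def test_hwe_violating_site_dropped():
    # site 0: AA=10, aa=10, no heterozygotes -> exact p << 1e-5
    haps = np.ones((40, 3), dtype=np.uint8)
    haps[:20, 0] = 0
    haps[::2, 1] = 0  # all het at site 1: p small too? counts (0,20,0)
    haps[: 10, 2] = 0
    haps[30:, 2] = 0  # mixed genotypes at site 2
    panel = build_panel(haps)
    filtered, report = qc_filter(panel, QCThresholds())
    removed = {c: ids for c, _, ids in report.steps}["hwe"]
    assert panel.snp_ids[0] in removed


def test_maf_and_monomorphic_sites_dropped():
    haps = np.zeros((40, 2), dtype=np.uint8)
    haps[0, 0] = 1  # MAF 1/40 = 0.025 retained at 0.01
    panel = build_panel(haps)
    filtered, report = qc_filter(panel, QCThresholds())
    # site 1 monomorphic: MAF 0 < 0.01 -> dropped
    assert filtered.n_sites == 1


def test_qc_filter_idempotent():
    rng = np.random.default_rng(5)
    panel = _qc_panel_with_missing(rng)
    once, _ = qc_filter(panel, QCThresholds())
    twice, report2 = qc_filter(once, QCThresholds())
    assert twice.n_sites == once.n_sites
    assert twice.n_samples == once.n_samples
    assert all(n == 0 for _, n, _ in report2.steps)


def test_all_samples_removed_is_an_error():
    panel = build_panel(np.zeros((4, 2), dtype=np.uint8))
    thr = QCThresholds(relatedness_exclusions=["s0", "s1"])
    with pytest.raises(ValueError):
        qc_filter(panel, thr)


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------

def test_end_masks_keep_interior_only():
    positions = np.array([1, 100_000, 200_000, 200_001, 500_000, 800_000, 800_001, 999_999])
    panel = build_panel(
        np.zeros((2, len(positions)), dtype=np.uint8), positions=positions
    )
    out = apply_masks(panel, {"1": ChromExtent(1, 1_000_000)}, QCThresholds())
    assert out.positions.tolist() == [200_001, 500_000, 800_000]


def test_extra_mask_can_empty_panel():
    panel = build_panel(np.zeros((2, 3), dtype=np.uint8), positions=[10, 20, 30])
    thr = QCThresholds(end_mask_bp=0, extra_masks=[("1", 1, 100)])
    out = apply_masks(panel, {"1": ChromExtent(1, 100)}, thr)
    assert out.n_sites == 0


def test_masks_match_brute_force_interval_oracle():
    rng = np.random.default_rng(9)
    positions = np.sort(rng.choice(np.arange(1, 1_000_001), size=1000, replace=False))
    panel = build_panel(np.zeros((2, 1000), dtype=np.uint8), positions=positions)
    ext = ChromExtent(1, 1_000_000, centromere=(450_000, 470_000))
    thr = QCThresholds(end_mask_bp=200_000, extra_masks=[("1", 600_000, 650_000)])
    out = apply_masks(panel, {"1": ext}, thr)
    m = thr.end_mask_bp
    expected = [
        int(p)
        for p in positions
        if (p - ext.start) >= m
        and (ext.end - p) >= m
        and not ((450_000 - p) < m and (p - 470_000) < m)
        and not (600_000 <= p <= 650_000)
    ]
    assert out.positions.tolist() == expected
    # with end masks only, ~600 of 1000 uniform sites on 1 Mb survive
    ends_only = apply_masks(
        panel, {"1": ChromExtent(1, 1_000_000)}, QCThresholds(end_mask_bp=200_000)
    )
    assert 550 <= ends_only.n_sites <= 650


def test_masking_commutes_with_qc_on_disjoint_criteria():
    rng = np.random.default_rng(21)
    panel = _qc_panel_with_missing(rng, n_samples=10, n_sites=60)
    ext = {"1": ChromExtent(1, 61_000)}
    thr = QCThresholds(end_mask_bp=10_000)
    a, _ = qc_filter(apply_masks(panel, ext, thr), thr)
    b = apply_masks(qc_filter(panel, thr)[0], ext, thr)
    assert a.positions.tolist() == b.positions.tolist()


def test_read_bed_converts_to_one_based_closed(tmp_path):
    bed = tmp_path / "m.bed"
    bed.write_text("1\t0\t100\n2\t500\t600\n")
    assert read_bed(bed) == [("1", 1, 100), ("2", 501, 600)]
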