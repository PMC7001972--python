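"""EHH profiles and integrals against brute-force pair counting."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from ehhscan import (
    EHHProfile,
    InsufficientCarriersError,
    ehh_profile,
    integrate_ehh,
    integrated_ehh,
    integrated_site_ehh,
    site_ehh_profile,
    profiles_to_frame,
)

from conftest import build_panel, random_panel


def ehh_pair_oracle(haps, carriers, core, x):
    """EHH by enumerating all carrier pairs over [core..x] inclusive."""
    lo, hi = min(core, x), max(core, x)
    n = len(carriers)
    if n < 2:
        raise ValueError("undefined")
    same = sum(
        1
        for a, b in combinations(carriers, 2)
        if np.array_equal(haps[a, lo : hi + 1], haps[b, lo : hi + 1])
    )
    return same / (n * (n - 1) / 2)


def ehhs_pair_oracle(haps, core, x):
    """Pooled site-EHH: identity fraction over [core..x], normalized at core."""
    n = haps.shape[0]
    lo, hi = min(core, x), max(core, x)

    def hh(a, b):
        return sum(
            1
            for i, j in combinations(range(n), 2)
            if np.array_equal(haps[i, a : b + 1], haps[j, a : b + 1])
        ) / (n * (n - 1) / 2)

    return hh(lo, hi) / hh(core, core)


def test_profile_matches_hand_example_two_two_split():
    # 4 derived carriers split 2/2 at the first flanking marker:
    # EHH = (C(2,2)+C(2,2))/C(4,2) = 1/3
    haps = np.array(
        [
            [1, 0],
            [1, 0],
            [1, 1],
            [1, 1],
            [0, 0],
            [0, 1],
        ],
        dtype=np.uint8,
    )
    panel = build_panel(haps)
    left, right = ehh_profile(panel, 0, "derived")
    assert right.ehh[0] == 1.0
    assert right.ehh[1] == pytest.approx(1 / 3)


def test_identical_carriers_keep_ehh_one_and_distinct_carriers_zero():
    haps = np.vstack([np.tile([1, 0, 1, 0, 1], (4, 1)), np.zeros((2, 5), np.uint8)])
    haps[4:, 0] = 0
    panel = build_panel(haps.astype(np.uint8))
    _, right = ehh_profile(panel, 0, "derived")
    assert np.all(right.ehh == 1.0)

    distinct = np.array(
        [[1, 0, 0], [1, 1, 0], [1, 0, 1], [1, 1, 1], [0, 0, 0], [0, 0, 0]],
        dtype=np.uint8,
    )
    panel2 = build_panel(distinct)
    _, r2 = ehh_profile(panel2, 0, "derived")
    assert r2.ehh[1] == pytest.approx(1 / 3)  # pairs within {00,10,01,11} groups
    assert r2.ehh[2] == 0.0


def test_single_carrier_is_undefined_not_zero():
    haps = np.zeros((4, 3), dtype=np.uint8)
    haps[0, 1] = 1
    panel = build_panel(haps)
    with pytest.raises(InsufficientCarriersError):
        ehh_profile(panel, 1, "derived")


def test_profiles_equal_pair_counting_oracle_small_panels():
    rng = np.random.default_rng(42)
    for _ in range(25):
        n_hap = int(rng.integers(4, 13))
        n_sites = int(rng.integers(4, 21))
        panel = random_panel(rng, n_hap=n_hap, n_sites=n_sites)
        core = int(rng.integers(0, n_sites))
        dh = panel.derived_haplotypes()
        for cls, allele in (("ancestral", 0), ("derived", 1)):
            carriers = np.nonzero(dh[:, core] == allele)[0]
            if len(carriers) < 2:
                continue
            left, right = ehh_profile(panel, core, cls)
            for prof, step in ((left, -1), (right, 1)):
                cols = range(core + step, -1 if step < 0 else n_sites, step)
                for t, x in enumerate(cols, start=1):
                    assert prof.ehh[t] == pytest.approx(
                        ehh_pair_oracle(panel.haplotypes, carriers, core, x)
                    ), (cls, core, x)


def test_pooled_profile_equals_pair_oracle_and_is_one_at_core():
    rng = np.random.default_rng(17)
    for _ in range(10):
        panel = random_panel(rng, n_hap=6, n_sites=8)
        core = int(rng.integers(0, 8))
        left, right = site_ehh_profile(panel, core)
        assert left.ehh[0] == 1.0 and right.ehh[0] == 1.0
        for prof, step in ((left, -1), (right, 1)):
            cols = range(core + step, -1 if step < 0 else 8, step)
            for t, x in enumerate(cols, start=1):
                assert prof.ehh[t] == pytest.approx(
                    ehhs_pair_oracle(panel.haplotypes, core, x)
                )


def test_profiles_monotone_non_increasing():
    rng = np.random.default_rng(99)
    for _ in range(20):
        panel = random_panel(rng, n_hap=10, n_sites=15)
        core = int(rng.integers(0, 15))
        for cls in ("ancestral", "derived"):
            try:
                left, right = ehh_profile(panel, core, cls)
            except InsufficientCarriersError:
                continue
            assert np.all(np.diff(left.ehh) <= 1e-12)
            assert np.all(np.diff(right.ehh) <= 1e-12)


def _profile(points, side, core_pos=0):
    d = np.array([p[0] for p in points])
    e = np.array([p[1] for p in points])
    return EHHProfile(
        core_index=0, core_pos=core_pos, chrom="1", allele_class="derived",
        side=side, distances=d, ehh=e, n_carriers=4,
    )


def test_integrate_hand_trapezoid():
    left = _profile([(0, 1.0)], "left")
    right = _profile([(0, 1.0), (10_000, 1 / 3), (20_000, 0.0)], "right")
    res = integrate_ehh(left, right, ehh_floor=0.05)
    assert res.area == pytest.approx(6666.67 + 1666.67, abs=0.5)
    assert res.truncated_left  # empty side never reached the floor
    assert not res.truncated_right


def test_integrate_floor_rules():
    left = _profile([(0, 1.0)], "left")
    # already below floor at the first marker: only that trapezoid counts
    right = _profile([(0, 1.0), (1000, 0.01), (2000, 0.0)], "right")
    res = integrate_ehh(left, right, ehh_floor=0.05)
    assert res.area == pytest.approx(0.5 * (1 + 0.01) * 1000)
    # flat at 1 over 50 kb: full rectangle, truncation flagged
    right2 = _profile([(0, 1.0), (50_000, 1.0)], "right")
    res2 = integrate_ehh(left, right2, ehh_floor=0.05)
    assert res2.area == pytest.approx(50_000)
    assert res2.truncated_right


def test_integration_linear_under_distance_rescaling():
    left = _profile([(0, 1.0), (5_000, 0.4), (9_000, 0.02)], "left")
    right = _profile([(0, 1.0), (7_000, 0.5), (15_000, 0.01)], "right")
    base = integrate_ehh(left, right).area
    left2 = _profile([(0, 1.0), (10_000, 0.4), (18_000, 0.02)], "left")
    right2 = _profile([(0, 1.0), (14_000, 0.5), (30_000, 0.01)], "right")
    assert integrate_ehh(left2, right2).area == pytest.approx(2 * base)


def test_fast_integrals_agree_with_profile_integration():
    rng = np.random.default_rng(5)
    for _ in range(15):
        panel = random_panel(rng, n_hap=12, n_sites=18)
        core = int(rng.integers(0, 18))
        dh = panel.derived_haplotypes()
        if min((dh[:, core] == 0).sum(), (dh[:, core] == 1).sum()) < 2:
            continue
        integ = integrated_ehh(panel, core)
        for cls, area in (
            ("ancestral", integ.ihh_ancestral),
            ("derived", integ.ihh_derived),
        ):
            left, right = ehh_profile(panel, core, cls)
            assert area == pytest.approx(integrate_ehh(left, right).area)
        ies, _ = integrated_site_ehh(panel, core)
        l, r = site_ehh_profile(panel, core)
        assert ies == pytest.approx(integrate_ehh(l, r).area)


def test_profile_export_frame_columns():
    rng = np.random.default_rng(1)
    panel = random_panel(rng, n_hap=6, n_sites=6)
    left, right = site_ehh_profile(panel, 3)
    df = profiles_to_frame([left, right])
    assert list(df.columns) == [
        "core_chrom", "core_pos", "allele_class", "side", "distance_bp", "ehh",
    ]
    assert set(df["side"]) == {"left", "right"}
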