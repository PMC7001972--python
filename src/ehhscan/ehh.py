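"""Extended haplotype homozygosity around a core SNP.

EHH at a marker x, for the haplotypes carrying a given core allele, is the
probability that two randomly drawn carriers are identical at every site
between the core and x inclusive:

    EHH(x) = sum_g C(c_g, 2) / C(n, 2)

where the c_g are the sizes of the distinct extended haplotypes among the
n carriers.  The pooled site statistic (EHHS) applies the same identity
count to all haplotypes, normalized by the haplotype homozygosity at the
core itself, so that it equals 1 at distance 0.  Integrating either curve
over physical distance (trapezoids, stopping at a small floor) gives iHH
per core allele, or iES for the pooled curve — the raw material for iHS
and XP-EHH.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .panel import ANC_UNKNOWN, HaplotypePanel

__all__ = [
    "EHHProfile", "IntegratedEHH", "InsufficientCarriersError",
    "ehh_profile", "site_ehh_profile", "integrate_ehh",
    "integrated_ehh", "integrated_site_ehh", "profiles_to_frame",
]

DEFAULT_EHH_FLOOR = 0.05


class InsufficientCarriersError(ValueError):
    """Fewer than two haplotypes carry the requested core allele."""


@dataclass
class EHHProfile:
    """EHH decay on one side of a core SNP.

    ``distances`` are non-negative bp offsets from the core, starting at 0
    where ``ehh`` is 1 by construction, and strictly increasing out to the
    panel edge.
    """

    core_index: int
    core_pos: int
    chrom: str
    allele_class: str  # 'ancestral' | 'derived' | 'pooled'
    side: str  # 'left' | 'right'
    distances: np.ndarray
    ehh: np.ndarray
    n_carriers: int

    @property
    def points(self) -> list[tuple[int, float]]:
        return list(zip(self.distances.tolist(), self.ehh.tolist()))


@dataclass
class IntegratedEHH:
    """Integrated EHH areas around one core SNP (bp-scaled)."""

    ihh_ancestral: float
    ihh_derived: float
    truncated_ancestral: bool
    truncated_derived: bool


def _carrier_rows(panel: HaplotypePanel, core: int, allele_class: str) -> np.ndarray:
    dh = panel.derived_haplotypes()
    if panel.ancestral_is_ref[core] == ANC_UNKNOWN:
        raise ValueError(
            f"core site {panel.chrom}:{panel.positions[core]} has unknown polarity"
        )
    want = 1 if allele_class == "derived" else 0
    return np.nonzero(dh[:, core] == want)[0].astype(np.int64)


def _side_profile(
    panel: HaplotypePanel,
    rows: np.ndarray,
    init_ids: np.ndarray,
    n_groups0: int,
    core: int,
    side: str,
    norm: float,
    allele_class: str,
) -> EHHProfile:
    step = -1 if side == "left" else 1
    vals = _kernels.ehh_values_side(
        panel.haplotypes, rows, init_ids, n_groups0, core, step, norm
    )
    if side == "left":
        cols = np.arange(core - 1, -1, -1)
    else:
        cols = np.arange(core + 1, panel.n_sites)
    dist = np.abs(panel.positions[cols] - panel.positions[core])
    return EHHProfile(
        core_index=core,
        core_pos=int(panel.positions[core]),
        chrom=panel.chrom,
        allele_class=allele_class,
        side=side,
        distances=np.concatenate(([0], dist)).astype(np.int64),
        ehh=np.concatenate(([1.0], vals)),
        n_carriers=int(rows.size),
    )


def ehh_profile(
    panel: HaplotypePanel, core: int, allele_class: str
) -> tuple[EHHProfile, EHHProfile]:
    """EHH decay profiles (left, right) for one core-allele class.

    Raises :class:`InsufficientCarriersError` when fewer than two
    haplotypes carry the requested allele — undefined, as distinct from an
    EHH of zero.
    """
    if allele_class not in ("ancestral", "derived"):
        raise ValueError("allele_class must be 'ancestral' or 'derived'")
    rows = _carrier_rows(panel, core, allele_class)
    if rows.size < 2:
        raise InsufficientCarriersError(
            f"{allele_class} allele at {panel.chrom}:{panel.positions[core]} "
            f"has {rows.size} carrier(s)"
        )
    init = np.zeros(rows.size, dtype=np.int64)
    left = _side_profile(panel, rows, init, 1, core, "left", 1.0, allele_class)
    right = _side_profile(panel, rows, init, 1, core, "right", 1.0, allele_class)
    return left, right


def _pooled_init(panel: HaplotypePanel, core: int) -> tuple[np.ndarray, np.ndarray, int, float]:
    rows = np.arange(panel.n_haplotypes, dtype=np.int64)
    if rows.size < 2:
        raise InsufficientCarriersError("need at least two haplotypes")
    alleles = panel.haplotypes[:, core].astype(np.int64)
    # compress 0/1 alleles to dense labels
    _, init = np.unique(alleles, return_inverse=True)
    init = init.astype(np.int64)
    n_groups0 = int(init.max()) + 1
    n = rows.size
    counts = np.bincount(init)
    hh0 = float((counts * (counts - 1)).sum() / 2.0) / (n * (n - 1) / 2.0)
    if hh0 == 0.0:
        raise InsufficientCarriersError(
            "core haplotype homozygosity is zero; pooled EHH undefined"
        )
    return rows, init, n_groups0, hh0


def site_ehh_profile(
    panel: HaplotypePanel, core: int
) -> tuple[EHHProfile, EHHProfile]:
    """Pooled (site) EHH decay, normalized to 1 at the core.

    Defined for any core, monomorphic included: the partition starts from
    the core alleles and the curve is divided by the core haplotype
    homozygosity.
    """
    rows, init, n_groups0, hh0 = _pooled_init(panel, core)
    left = _side_profile(panel, rows, init, n_groups0, core, "left", hh0, "pooled")
    right = _side_profile(panel, rows, init, n_groups0, core, "right", hh0, "pooled")
    return left, right


@dataclass
class SideIntegral:
    area: float
    truncated_left: bool
    truncated_right: bool


def integrate_ehh(
    left: EHHProfile, right: EHHProfile, ehh_floor: float = DEFAULT_EHH_FLOOR
) -> SideIntegral:
    """Trapezoid integral of a two-sided decay curve over physical distance.

    On each side the walk proceeds marker to marker and stops at the first
    marker where EHH < floor; that marker's trapezoid is included and
    everything beyond it is not.  ``truncated`` flags a side whose floor
    was never reached before the panel edge.  An empty side contributes
    area 0 with its truncation flag set.
    """
    if not 0.0 <= ehh_floor < 1.0:
        raise ValueError("ehh_floor must be in [0, 1)")
    if (left.core_index, left.core_pos) != (right.core_index, right.core_pos):
        raise ValueError("profiles do not share a core")
    total = 0.0
    flags = []
    for prof in (left, right):
        area = 0.0
        truncated = True
        for k in range(1, len(prof.distances)):
            area += (
                0.5
                * (prof.ehh[k - 1] + prof.ehh[k])
                * (prof.distances[k] - prof.distances[k - 1])
            )
            if prof.ehh[k] < ehh_floor:
                truncated = False
                break
        total += area
        flags.append(truncated)
    return SideIntegral(area=total, truncated_left=flags[0], truncated_right=flags[1])


def _ihh_class(
    panel: HaplotypePanel, core: int, allele_class: str, ehh_floor: float
) -> tuple[float, bool]:
    rows = _carrier_rows(panel, core, allele_class)
    if rows.size < 2:
        raise InsufficientCarriersError(
            f"{allele_class} allele at core {core} has {rows.size} carrier(s)"
        )
    init = np.zeros(rows.size, dtype=np.int64)
    a_l, t_l = _kernels.ihh_side(
        panel.haplotypes, rows, init, 1, core, -1, panel.positions, ehh_floor, 1.0
    )
    a_r, t_r = _kernels.ihh_side(
        panel.haplotypes, rows, init, 1, core, 1, panel.positions, ehh_floor, 1.0
    )
    return a_l + a_r, bool(t_l or t_r)


def integrated_ehh(
    panel: HaplotypePanel, core: int, ehh_floor: float = DEFAULT_EHH_FLOOR
) -> IntegratedEHH:
    """iHH for the ancestral and derived allele classes at one core SNP."""
    ihh_a, trunc_a = _ihh_class(panel, core, "ancestral", ehh_floor)
    ihh_d, trunc_d = _ihh_class(panel, core, "derived", ehh_floor)
    return IntegratedEHH(
        ihh_ancestral=ihh_a,
        ihh_derived=ihh_d,
        truncated_ancestral=trunc_a,
        truncated_derived=trunc_d,
    )


def integrated_site_ehh(
    panel: HaplotypePanel, core: int, ehh_floor: float = DEFAULT_EHH_FLOOR
) -> tuple[float, bool]:
    """iES: integral of the pooled site-EHH curve; returns (area, truncated)."""
    rows, init, n_groups0, hh0 = _pooled_init(panel, core)
    a_l, t_l = _kernels.ihh_side(
        panel.haplotypes, rows, init, n_groups0, core, -1, panel.positions, ehh_floor, hh0
    )
    a_r, t_r = _kernels.ihh_side(
        panel.haplotypes, rows, init, n_groups0, core, 1, panel.positions, ehh_floor, hh0
    )
    return a_l + a_r, bool(t_l or t_r)


def profiles_to_frame(profiles: list[EHHProfile]) -> pd.DataFrame:
    """Long-format table of decay curves for export/plotting."""
    rows = []
    for p in profiles:
        for d, e in zip(p.distances, p.ehh):
            rows.append(
                {
                    "core_chrom": p.chrom,
                    "core_pos": p.core_pos,
                    "allele_class": p.allele_class,
                    "side": p.side,
                    "distance_bp": int(d),
                    "ehh": float(e),
                }
            )
    return pd.DataFrame(rows)
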