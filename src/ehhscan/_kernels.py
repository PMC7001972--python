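"""Numba kernels for EHH decay and its physical-distance integral.

Both kernels walk outward from a core site, refining a partition of the
tracked haplotypes by the allele carried at each successive marker.  EHH at
a marker is the fraction of tracked haplotype pairs still identical over
the whole interval; the integral accumulates trapezoids in bp and stops at
the first marker where EHH drops below the floor (that trapezoid is the
last one included).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def ihh_side(haps, rows, init_ids, n_groups0, core, step, positions, floor, norm):
    """Integrate EHH over one side of the core.

    haps       uint8 (n_haplotypes, n_sites) full panel matrix
    rows       int64 indices of tracked haplotypes
    init_ids   int64 compressed starting partition labels (0..n_groups0-1)
    core       core site column; step +1 (right) or -1 (left)
    floor      stop once EHH < floor
    norm       homozygosity normalizer (1.0 for allele-class EHH; core
               haplotype homozygosity for the pooled site statistic)

    Returns (area_bp, truncated) where truncated is 1 if the panel edge was
    reached before the floor.
    """
    n = rows.shape[0]
    denom = n * (n - 1) / 2.0
    ids = init_ids.copy()
    counts = np.zeros(2 * n + 2, np.int64)
    labels = np.full(2 * n + 2, -1, np.int64)
    newkey = np.empty(n, np.int64)

    hh = 0.0
    for i in range(n):
        counts[ids[i]] += 1
    for g in range(n_groups0):
        c = counts[g]
        hh += c * (c - 1) / 2.0
        counts[g] = 0
    ehh_prev = hh / denom / norm
    pos_prev = positions[core]
    area = 0.0
    truncated = 1
    if ehh_prev < floor:
        return 0.0, 0
    j = core + step
    while 0 <= j < haps.shape[1]:
        for i in range(n):
            newkey[i] = ids[i] * 2 + haps[rows[i], j]
        nlab = 0
        for i in range(n):
            k = newkey[i]
            if labels[k] == -1:
                labels[k] = nlab
                nlab += 1
            ids[i] = labels[k]
        hh = 0.0
        for i in range(n):
            counts[ids[i]] += 1
        for g in range(nlab):
            c = counts[g]
            hh += c * (c - 1) / 2.0
            counts[g] = 0
        for i in range(n):
            labels[newkey[i]] = -1
        ehh = hh / denom / norm
        d = positions[j] - pos_prev
        if d < 0:
            d = -d
        area += 0.5 * (ehh_prev + ehh) * d
        pos_prev = positions[j]
        ehh_prev = ehh
        if ehh < floor:
            truncated = 0
            break
        j += step
    return area, truncated


@njit(cache=False)
def ehh_values_side(haps, rows, init_ids, n_groups0, core, step, norm):
    """EHH value at every marker from the core to the panel edge (one side).

    Returns a float64 array aligned with the walked columns (length
    ``core`` for the left side, ``n_sites - core - 1`` for the right).
    """
    n = rows.shape[0]
    denom = n * (n - 1) / 2.0
    n_out = core if step < 0 else haps.shape[1] - core - 1
    out = np.zeros(n_out, np.float64)
    ids = init_ids.copy()
    counts = np.zeros(2 * n + 2, np.int64)
    labels = np.full(2 * n + 2, -1, np.int64)
    newkey = np.empty(n, np.int64)
    j = core + step
    t = 0
    alive = True
    while 0 <= j < haps.shape[1]:
        if alive:
            for i in range(n):
                newkey[i] = ids[i] * 2 + haps[rows[i], j]
            nlab = 0
            for i in range(n):
                k = newkey[i]
                if labels[k] == -1:
                    labels[k] = nlab
                    nlab += 1
                ids[i] = labels[k]
            hh = 0.0
            for i in range(n):
                counts[ids[i]] += 1
            for g in range(nlab):
                c = counts[g]
                hh += c * (c - 1) / 2.0
                counts[g] = 0
            for i in range(n):
                labels[newkey[i]] = -1
            out[t] = hh / denom / norm
            if hh == 0.0:
                alive = False  # EHH stays 0 beyond total breakdown
        j += step
        t += 1
    return out
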