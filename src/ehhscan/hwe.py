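"""Exact test of Hardy-Weinberg equilibrium on diploid genotype counts.

The test conditions on the observed allele counts and enumerates every
possible heterozygote count, summing the probabilities of all genotype
configurations no more likely than the observed one (the conditional exact
test of Wigginton, Cutler & Abecasis; no mid-p correction).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

__all__ = ["hwe_exact_p"]


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact HWE p-value for one biallelic site.

    Parameters are diploid genotype counts. Returns 1.0 for monomorphic or
    empty sites (no evidence against equilibrium is possible).
    """
    n_hom_ref, n_het, n_hom_alt = int(n_hom_ref), int(n_het), int(n_hom_alt)
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n == 0 or n_rare == 0:
        return 1.0

    # All heterozygote counts compatible with the conditioned allele counts
    # share the parity of the rare-allele count.
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    valid = common_hom >= 0
    hets, rare_hom, common_hom = hets[valid], rare_hom[valid], common_hom[valid]

    # log P(het | allele counts) up to a shared constant:
    #   n! / (n_AA! n_Aa! n_aa!) * 2^het  (the hypergeometric-style kernel)
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(rare_hom + 1)
        - gammaln(common_hom + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[hets == n_het]
    if p_obs.size == 0:  # inconsistent counts cannot occur given parity
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    # Sum of configurations no more probable than observed; small tolerance
    # keeps ties stable under floating-point noise.
    return float(min(1.0, prob[prob <= p_obs[0] * (1 + 1e-12)].sum()))
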