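# Methods

## Scope

`ehhscan` implements a genome scan for recent positive selection on
phased haplotype panels, combining four layers of evidence:

1. **iHS** — within one population, the log ratio of integrated EHH
   around the ancestral versus the derived allele of each SNP,
   standardized within derived-allele-frequency bins.
2. **XP-EHH** — between a test and a reference population, the log ratio
   of integrated pooled site-EHH, standardized genome-wide; only positive
   outliers (longer haplotypes in the test population) are called.
3. **Window outliers** — non-overlapping 100 kb windows holding at least
   two SNPs in the extreme tail of the empirical |score| distribution,
   intersected across populations.
4. **Allele-frequency over-representation** — samples pooled into
   population groups; sites where a designated test group's
   derived-allele frequency is both high and several times the maximum
   over all other groups, with permutation (Monte-Carlo) significance.

A forward-time Wright-Fisher simulator generates multi-population phased
panels with planted sweeps as ground truth for every layer.

## EHH statistics

For the n haplotypes carrying a given core allele, EHH at a marker x is
the probability that two randomly drawn carriers are identical at every
site between the core and x inclusive:

    EHH(x) = sum_g C(c_g, 2) / C(n, 2),

with c_g the sizes of the distinct extended haplotypes.  The pooled site
statistic (EHHS) applies the same count to all haplotypes and divides by
the haplotype homozygosity at the core itself, so it equals 1 at distance
zero regardless of the core's frequency.  Identity is exact allele-string
matching over the intervening markers; sites of unknown ancestral state
may serve as extension markers (identity does not need polarity) but
never as cores.

**Integration.** iHH (per allele class) and iES (pooled) are trapezoid
integrals of the decay curve over physical distance, walked marker to
marker away from the core.  Integration stops at the first marker where
the curve falls below a floor of 0.05 — that trapezoid is included,
later ones are not — matching the default of the established R
implementation of these statistics.  A side whose floor is never reached
before the panel edge is flagged truncated.  No gap penalty or maximum
gap is applied by default (both exist as hooks).  Distances are physical
(bp); genetic-map distances are out of scope.

**Computation.** Both curves are computed by partition refinement: walk
outward, refine the current grouping of haplotypes by the allele at the
next marker, and accumulate pair counts.  The kernels are numba-compiled
(O(n) per marker per core) and are checked exactly against a brute-force
pair-enumeration oracle on small panels in the test suite.

## iHS

uiHS = ln(iHH_ancestral / iHH_derived); negative values mean long
derived haplotypes (a sweep on the derived allele).  SNPs are scored only
when polarity is known and derived frequency lies in [0.05, 0.95] (the
established default).  Because the null distribution of uiHS depends
strongly on derived-allele frequency, scores are z-standardized within
frequency bins of width 0.025; bins with fewer than 10 scored SNPs merge
with their neighbor toward frequency 0.5; the sample standard deviation
(ddof = 1) is used, so each bin's standardized scores have exactly zero
mean and unit sd.  A zero-variance bin leaves its SNPs flagged rather
than scored.  Two-sided Gaussian p-values follow:
−log10 p = −log10(2 Φ(−|iHS|)), computed in log space.  The per-SNP
"selected allele" is the class with the larger iHH.  SNPs significant in
two or more populations are collected into a coincidence table;
co-significant SNPs within 500 bp are annotated as one locus (raw rows
preserved).

## XP-EHH

For a (test, reference) pair restricted to shared sites polymorphic in
the pooled pair, the unstandardized score is ln(iES_test / iES_ref) —
antisymmetric under exchanging the panels, and identically zero when they
coincide.  Standardization is genome-wide per pair (the frequency-binning
rationale applies to iHS only).  Significance requires the two-sided
Gaussian p at or below threshold AND a positive score, since negative
outliers point at the reference population.  Significant SNPs across all
(population, reference) pairs merge into loci within 100 kb; the pattern
matrix lists, per locus and population, the single-letter labels of the
references under which the signal appears.  The Sabeti-style iES
(EHHS normalized by core homozygosity) is the default.

## Window scan

Windows are half-open [k·w, (k+1)·w), anchored at coordinate 0 with
w = 100 kb; a SNP on a boundary belongs to the right window.  The
threshold is the nearest-rank (1 − tail) quantile of |score| — the
ceil(n(1−tail))-th order statistic — computed per population over its own
scanned SNPs, with tail = 0.001 by default.  A window qualifies with at
least two SNPs at or above threshold; cross-population windows qualify in
two or more populations on the same grid.  On panel-scale test data
(hundreds of scored SNPs) a 0.1% tail degenerates to the sample maximum,
so fixture-level demonstrations use a 1% tail; the definition is
unchanged.

## Over-representation scan

Diploid derived-allele dosages are pooled into groups
(frequency = count / 2·group size).  A site qualifies when the test
group's frequency exceeds a floor and the ratio to the **maximum**
frequency over all other groups reaches a multiple (the pooled-remainder
denominator is a config option).  Mode defaults: locus (floor 0.20,
ratio 2.0, ±0.8 Mb windows around seed positions, explicit "Not found"
rows for empty windows), genome (0.25, 3.0, intersected with EHH-signal
positions within 0.8 Mb, qualifying SNPs clustered into loci within
500 kb), missense (0.20, 1.8, restricted to sites annotated missense in a
supplied consequence table).  A zero denominator yields an infinite
ratio, which always passes and is flagged.  Ratio comparisons carry a
1e-9 absolute slack to absorb float-division noise at exact multiples.
Locus spans are last − first position in bp, rounded to the nearest kb;
a single-SNP locus has no span.  Reported ratios also appear as floors
("≥ xF") rounded down to one decimal, matching how such tables are
printed.

**Monte-Carlo significance.** The null permutes sample-to-group labels,
preserving group sizes — an exchangeable null chosen because it assumes
nothing about the frequency distribution.  The statistic is the best
qualifying ratio anywhere in the tested locus; with k of N permutations
reaching the observed value, p = (k + 1)/(N + 1), floored at 1/(N+1) and
never zero.  Under a fully exchangeable data-generating process these
p-values are (super-)uniform, which the suite verifies by KS test.  An
optional Gaussian tail approximation to the permutation distribution is
available (labeled) for p-values beyond the permutation floor.

## QC and masking

Order of application: explicit relatedness exclusion list (IBD estimation
itself is out of scope), sample call rate ≥ 0.95, SNP missing rate
≤ 0.05, MAF ≥ 0.01, exact HWE p ≥ 1e-5.  The HWE test is the conditional
exact test on diploid genotype counts (enumeration over heterozygote
counts, no mid-p), evaluated within each population when a population map
is supplied (a site fails if any population fails) and pooled otherwise.
Sites still carrying missing genotypes after these filters are dropped:
the EHH machinery assumes complete haplotypes and nothing is imputed.
QC is idempotent by construction.  Masks remove sites whose distance to a
chromosome end or to the centromere interval is below 200 kb, plus any
extra intervals (e.g. the MHC); coordinates are 1-based closed
throughout, with BED inputs converted on read.  The pipeline applies QC
to the combined multi-population panel (the shared-SNP framing of a
cross-population study), then splits per population; this keeps sites
monomorphic in a reference but swept in a test population — exactly the
XP-EHH targets — in the analysis.

## Synthetic data

The simulator is forward-time Wright-Fisher, chosen over coalescent
machinery so that every mechanism (selection, recombination, drift,
population splits) is explicit and auditable; an msprime-based
cross-check was used during development as an independent sanity oracle
for the statistics.

* **Founders and LD.** Founder haplotypes are drawn site-wise from a
  Beta(1, 1) frequency spectrum — a flat founder MAF spectrum emulating
  the ascertainment of genotyping arrays toward common variants — so the
  pool starts in linkage equilibrium and LD accrues through drift during
  a burn-in of roughly the population's coalescent timescale before any
  split.
* **Transmission.** Each offspring haplotype copies one parent's pair
  with crossovers falling as independent Bernoulli events per inter-site
  interval (probability r × gap bp), sampled sparsely and exactly.
  Parents are drawn with probability proportional to fitness (1, 1+hs,
  1+s by focal genotype) when selection is active.  There is no
  recurrent mutation after founding: sites stay biallelic, as on arrays.
* **Scaled parameters.** Census sizes are far below human effective
  sizes, so the per-bp recombination rate is scaled up in compensation
  (default r = 2e-7 with censuses of a few hundred diploids keeps
  ρ = 4Nr per bp near the human-like 1e-4–4e-4 range).  This matters:
  with unscaled r the EHH floor is never reached inside the simulated
  window and the integrals truncate at the panel edges, erasing the
  contrast the statistics measure.  Panels are samples: the census
  population evolves and a smaller sample of diploids is drawn at the
  end, as in a real study.
* **Sweeps.** The focal site is monomorphic ancestral until the onset
  generation, when the derived allele is introduced on
  max(1, round(start_freq × 2N)) haplotypes — a single new copy by
  default (hard sweep).  Because new copies are usually lost, the run
  checkpoints the population at onset and re-draws the post-onset phase
  until the allele establishes and its final frequency lies inside an
  acceptance window (incomplete-sweep sampling; iHS is known to have
  power mainly for derived frequencies around 0.6–0.9, and degenerates
  as frequency approaches 1).  For a sweep confined to one deme this
  conditioning is exact and cheap: a one-locus frequency trajectory is
  pre-drawn under WF selection conditioned on survival and the
  structured simulation then matches it generation by generation, each
  offspring's recombinant mosaic anchored at the focal site.  Multi-deme
  (shared) sweeps use checkpointed re-introduction with spawned RNG
  streams.  Within-class anchor parents are drawn uniformly rather than
  fitness-weighted — a second-order approximation under conditioning.
  A sweep introduced in the pool before the splits is shared identically
  by descent across the daughter populations.
* **Truth.** The ancestral allele of every site is the founder-majority
  allele (ties to REF), giving a consistent polarization truth; the
  sweep truth (focal position, s, h, target populations, realized
  frequencies, retry count, seed) accompanies every panel.  Identical
  config and seed give byte-identical output bundles.

**What the generator does not emulate:** mutation accumulation,
genotyping error and missingness, ascertainment bias beyond the flat
founder spectrum, realistic human demographies, varying recombination
maps, background selection.  Passing tests therefore demonstrate the
correctness and calibration of the statistics under a clean WF model,
not their power on any particular real cohort.

## Named scenarios and problem sizes

`make_fixture` freezes six seeded scenarios; the defaults are the study
conditions of every statistical test in the suite:

| scenario | pops × census (sample) | sites / length | sweep |
|---|---|---|---|
| neutral_single | 1 × 250 (100) | 1500 / 3 Mb | none |
| neutral_multi | 3 × 250 (60) | 1200 / 2.4 Mb | none |
| sweep_single | 1 × 500 (200) | 5000 / 10 Mb | s=0.1, hard, final freq 0.6–0.9 |
| sweep_shared | 3 × 400 (100) | 1500 / 3 Mb | s=0.1, pre-split onset, all pops |
| sweep_private | 3 × 250 (60) | 1500 / 3 Mb | s=0.12, pop1 only, final 0.7–0.97 |
| freqscan_differentiated | 12 × 120 (14–25) | 1200 / 2.4 Mb | s=0.15 in the NWA-like group |

The sweep-recovery check runs 20 sweep_single replicates and asks that
the focal SNP's |iHS| exceed the 99th percentile of the same replicate's
neutral SNPs — scored SNPs more than 1 Mb from the focal site, since
hitchhikers within the sweep's reach are not neutral controls — in the
majority of replicates.  These sizes keep the full suite and the
acceptance script at desk scale (minutes on one CPU).

## Numerical choices and degenerate inputs

* EHH with fewer than two carriers raises a distinct error (undefined,
  not zero); zero iHH or iES excludes a SNP with a recorded reason.
* Frequency-bin edges are right-open except the last; floating-point
  edge effects at exact bin boundaries are accepted (bin membership is a
  measure-zero concern on real data).
* The nearest-rank window threshold is always an observed order
  statistic; when all scores tie, every window with enough SNPs
  qualifies (degenerate but well-defined).
* Permutation p-values are never zero; ties count in favor of the null
  (stat ≥ observed).
* Masking distance is strict (< mask bp removed), so a site exactly at
  mask distance survives.
* All randomness flows through numpy Generators seeded from explicit
  seeds; retries use SeedSequence spawn keys so different base seeds
  can never collide on a stream.

## Known limitations

* Single-chromosome panels; multi-chromosome studies run the pipeline
  per chromosome and concatenate score tables before standardization if
  genome-wide bins are wanted.
* Physical distance only (no genetic maps, no gap scaling by default).
* The Monte-Carlo null treats samples as exchangeable across groups;
  real population structure makes it conservative for close groups and
  anti-conservative for deeply diverged ones — it is a calibration
  statement about the label-permutation null, not a demographic model.
* Fixture-scale panels cannot reach genome-scale significance thresholds
  (p ≤ 1e-5 over ~10^3 SNPs); demonstrations at panel scale use looser
  thresholds and say so where they do.
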