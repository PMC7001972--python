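# ehhscan

Selection scans on phased haplotype panels: extended-haplotype-homozygosity
statistics (iHS, XP-EHH), empirical-tail window scans, and a group-pooled
allele-frequency over-representation scan with Monte-Carlo significance —
plus a forward-time Wright–Fisher simulator that generates multi-population
panels with planted selective sweeps as ground truth.

## The problem

A recent beneficial mutation rises in frequency faster than recombination
can shuffle its flanking haplotype, leaving an unusually long, unusually
frequent haplotype around the selected site.  Two classic statistics
quantify this:

* **iHS** compares the decay of extended haplotype homozygosity (EHH)
  around the ancestral versus the derived allele of each SNP within one
  population:

      uiHS = ln( iHH_A / iHH_D ),

  where iHH is the area under the EHH decay curve over physical distance.
  Raw scores are binned by derived-allele frequency and z-standardized
  within bins, so iHS is approximately standard normal and a two-sided
  Gaussian p applies: −log10 p = −log10(2 Φ(−|iHS|)).

* **XP-EHH** compares the integrated pooled site-EHH (iES) between a test
  and a reference population: ln(iES_test / iES_ref), standardized
  genome-wide.  Positive outliers mark haplotypes that stayed long in the
  test population after breaking down in the reference.

Around these sit the supporting layers a scan needs: phased-VCF input with
ancestral-allele polarization, array-style QC (call rate, missing rate,
MAF, exact Hardy–Weinberg test) with end/centromere masks, 100 kb window
outlier detection intersected across populations, and a whole-genome
allele-frequency scan that finds alleles several times more frequent in a
test group of populations than in every other group, with label-permutation
p-values.

It is written for population geneticists who want a self-contained,
fully tested scan pipeline they can run on their own phased panels or on
simulated data; every statistic is checked against brute-force oracles and
exercised end to end on simulations with known truth.

## Worked example

Generate a three-population panel in which a hard sweep (s = 0.12) is
private to `pop1`, then scan it:

```python
from ehhscan import make_fixture, ihs_scan, standardize, xpehh_scan

res = make_fixture("sweep_private", seed=1)       # panels + truth
print(res.truth.focal_position, res.truth.derived_freq)
# 1503003 {'pop1': 0.825, 'pop2': 0.0, 'pop3': 0.0}

table = standardize(ihs_scan(res.panels["pop1"])).scored()
print(float(table.loc[table.pos == 1503003, "ihs"].iloc[0]))
# -2.90  (long derived haplotypes -> strongly negative iHS)

xp = xpehh_scan(res.panels["pop1"], res.panels["pop2"], "pop1", "pop2")
row = xp.frame[xp.frame.pos == 1503003]
print(float(row.xpehh.iloc[0]))
# 2.76   (99.7th percentile of 1,039 scored SNPs)
```

The focal SNP carries a strongly negative iHS in the swept population and
one of the largest positive XP-EHH scores against the unswept reference —
the two signatures the pipeline is built to detect.

The numbered drivers under `analysis/` run the same machinery as a
narrative: `01_simulate_panels.py` writes the cohorts,
`02_qc_panels.py` QC-filters them through the file-based VCF path,
`03_ihs_scan.py`–`06_freq_scan.py` run the four scan layers and write
their tables under `results/`.  For shell use there is a thin CLI:

```bash
ehhscan simulate sweep_private --out fixture/ --seed 1
ehhscan run --config pipeline.yaml     # qc -> ihs -> xpehh -> windows -> freqscan -> report
```

## Layout

```
src/ehhscan/      library: panel IO/QC, EHH kernels, iHS, XP-EHH,
                  window scan, frequency scan, simulator, pipeline, CLI
analysis/         numbered narrative drivers writing results/
tests/            pytest suite (oracle, property and end-to-end checks)
scripts/          acceptance script
docs/methods.md   model, assumptions, parameter choices, limitations
```
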