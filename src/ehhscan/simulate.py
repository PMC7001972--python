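"""Forward-time Wright-Fisher simulator for multi-population phased panels.

Founder haplotypes are drawn site-wise from a Beta frequency spectrum, so
the ancestral pool starts in linkage equilibrium; drift during the shared
burn-in builds LD before populations split and diverge.  Each generation,
every offspring haplotype is a recombinant copy of one parent's two
haplotypes: parents are sampled with probability proportional to fitness
(1, 1+hs, 1+s by genotype at the focal site when a sweep is active), and
crossovers fall as independent Bernoulli events per inter-site interval
with probability recomb_rate * gap_bp.  Sites are biallelic with no
recurrent mutation, and the ancestral allele of every site is the founder
majority allele — a polarization truth the rest of the pipeline can be
checked against.

Sweeps are hard by default: the focal site is monomorphic ancestral until
the onset generation, when the derived allele is introduced on
``max(1, round(start_freq * 2N))`` pool haplotypes (``start_freq = 0``
means a single new copy).  Because a new beneficial copy is usually lost
to drift, the run checkpoints the population state at onset and re-draws
the post-onset phase — re-introducing the mutation, as recurrent mutation
would — until the allele establishes and its final frequency falls inside
the configured acceptance window in every target population.  Since the
default population sizes are scaled far below humans, the per-bp
recombination rate is scaled up in compensation (keeping 4Nr per bp in a
realistic range), so that EHH decays to its floor well inside the
simulated window.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .panel import (
    ANC_ALT, ANC_REF, HaplotypePanel, PopulationMap,
    write_phased_vcf, write_population_map,
)

__all__ = [
    "SweepConfig", "SimConfig", "SweepTruth", "SimResult",
    "simulate", "make_fixture", "SCENARIOS",
]

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


@dataclass
class SweepConfig:
    """A single selected site.

    Selection acts through ``h``: genotype fitnesses are 1, 1 + h*s,
    1 + s.  The derived allele is introduced in the shared pool at
    ``onset_generation`` (default: the earliest split of a target
    population) and selection acts from then on — in the pool while any
    target population has not yet split, and in each target population
    after its split.  A sweep introduced before the splits is therefore
    shared identically by descent across populations.
    """

    focal_site: int
    s: float
    h: float = 0.5
    start_freq: float = 0.0
    pops: tuple[str, ...] = ()
    onset_generation: int | None = None
    condition_on_sweep: bool = True
    # Accept an attempt only if the focal derived frequency ends inside
    # this window in every target population (incomplete-sweep sampling,
    # the regime where haplotype-length contrasts are defined); None
    # requires only that the allele still segregates.
    final_freq_range: tuple[float, float] | None = None
    max_retries: int = 500

    def __post_init__(self) -> None:
        if not 0.0 <= self.start_freq < 1.0:
            raise ValueError("start_freq must be in [0, 1)")


@dataclass
class SimConfig:
    """Study conditions for one simulated panel set."""

    seed: int
    n_pops: int = 1
    diploid_size: int | tuple[int, ...] = 200
    # diploids sampled into the output panel per population (census size
    # stays diploid_size; None samples everyone)
    sample_diploid_size: int | tuple[int, ...] | None = None
    pool_diploid_size: int | None = None
    split_schedule: tuple[int, ...] = (200,)
    n_generations: int = 290
    n_sites: int = 5000
    chrom_length_bp: int = 10_000_000
    recomb_rate: float = 2e-7
    init_freq_spectrum: tuple[float, float] = (1.0, 1.0)
    sweep: SweepConfig | None = None
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if isinstance(self.diploid_size, int):
            self.diploid_size = (self.diploid_size,) * self.n_pops
        self.diploid_size = tuple(self.diploid_size)
        if len(self.diploid_size) != self.n_pops:
            raise ValueError("diploid_size must match n_pops")
        if self.sample_diploid_size is None:
            self.sample_diploid_size = self.diploid_size
        elif isinstance(self.sample_diploid_size, int):
            self.sample_diploid_size = (self.sample_diploid_size,) * self.n_pops
        else:
            self.sample_diploid_size = tuple(self.sample_diploid_size)
        if any(
            s > c for s, c in zip(self.sample_diploid_size, self.diploid_size)
        ):
            raise ValueError("cannot sample more diploids than the census size")
        self.split_schedule = tuple(self.split_schedule)
        if len(self.split_schedule) not in (1, self.n_pops):
            raise ValueError("split_schedule must have 1 or n_pops entries")
        if len(self.split_schedule) == 1:
            self.split_schedule = self.split_schedule * self.n_pops
        if any(g < 0 or g > self.n_generations for g in self.split_schedule):
            raise ValueError("split generations must lie within the run")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be non-negative")
        if self.sweep is not None and not (
            0 <= self.sweep.focal_site < self.n_sites
        ):
            raise ValueError("focal_site out of range")

    @property
    def pop_names(self) -> list[str]:
        return [f"pop{i + 1}" for i in range(self.n_pops)]


@dataclass
class SweepTruth:
    """Ground truth written alongside every simulated panel."""

    focal_site: int | None
    focal_position: int | None
    s: float
    h: float
    pops: list[str]
    derived_freq: dict[str, float]
    lost: dict[str, bool]
    fixed: dict[str, bool]
    seed: int
    n_retries: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


@dataclass
class SimResult:
    panels: dict[str, HaplotypePanel]
    pop_map: PopulationMap
    ancestral: dict[tuple[str, int], str]
    truth: SweepTruth
    config: SimConfig

    def merged_panel(self) -> HaplotypePanel:
        from .panel import merge_panels

        return merge_panels(self.panels, order=self.config.pop_names)


def _crossover_events(
    n_hap: int, gaps_p: np.ndarray, rng: np.random.Generator
) -> dict[int, np.ndarray]:
    """Sparse Bernoulli crossovers: sorted gap indices per offspring row.

    Exact per-interval Bernoulli sampling, drawn gap-wise (a Binomial count
    per interval, then distinct rows) — crossovers are rare, so this is
    far cheaper than a dense draw.
    """
    ks = rng.binomial(n_hap, gaps_p)
    hit = np.nonzero(ks)[0]
    rows_list, gaps_list = [], []
    for j in hit:
        k = int(ks[j])
        if k == 1:
            rows_list.append(rng.integers(0, n_hap, size=1))
        else:
            rows_list.append(rng.choice(n_hap, size=k, replace=False))
        gaps_list.append(np.full(k, j, dtype=np.int64))
    if not rows_list:
        return {}
    rows = np.concatenate(rows_list)
    gaps = np.concatenate(gaps_list)
    order = np.lexsort((gaps, rows))
    rows, gaps = rows[order], gaps[order]
    out: dict[int, np.ndarray] = {}
    starts = np.nonzero(np.diff(rows, prepend=rows[0] - 1))[0]
    for i, s0 in enumerate(starts):
        s1 = starts[i + 1] if i + 1 < len(starts) else len(rows)
        out[int(rows[s0])] = gaps[s0:s1]
    return out


def _recombine(
    haps: np.ndarray,
    anchors: np.ndarray,
    partners: np.ndarray,
    gaps_p: np.ndarray,
    rng: np.random.Generator,
    anchor_site: int = 0,
) -> np.ndarray:
    """Recombinant offspring haplotypes anchored at one site.

    Offspring row i starts as a copy of ``haps[anchors[i]]``; moving
    outward from ``anchor_site``, each crossover switches the source
    between the anchor and its within-individual partner, so the allele
    at the anchor site always comes from the anchor haplotype.
    """
    child = haps[anchors].copy()
    n_hap, n_sites = child.shape
    if n_sites <= 1:
        return child
    events = _crossover_events(n_hap, gaps_p, rng)
    for i, gaps in events.items():
        partner = haps[partners[i]]
        right = gaps[gaps >= anchor_site]
        for m in range(0, len(right), 2):
            lo = right[m] + 1
            hi = right[m + 1] + 1 if m + 1 < len(right) else n_sites
            child[i, lo:hi] = partner[lo:hi]
        left = gaps[gaps < anchor_site][::-1]  # descending, outward
        for m in range(0, len(left), 2):
            hi = left[m] + 1
            lo = left[m + 1] + 1 if m + 1 < len(left) else 0
            child[i, lo:hi] = partner[lo:hi]
    return child


def _wf_generation(
    haps: np.ndarray,
    gaps_p: np.ndarray,
    rng: np.random.Generator,
    focal: int | None,
    s: float,
    h: float,
) -> np.ndarray:
    """One Wright-Fisher generation for a population of 2N haplotypes."""
    n_hap, n_sites = haps.shape
    n_dip = n_hap // 2
    if focal is not None and s != 0.0:
        geno = haps[0::2, focal].astype(np.int64) + haps[1::2, focal]
        w = 1.0 + np.where(geno == 2, s, 0.0) + np.where(geno == 1, h * s, 0.0)
        w = w / w.sum()
        parents = rng.choice(n_dip, size=n_hap, p=w)
    else:
        parents = rng.integers(0, n_dip, size=n_hap)
    start = rng.integers(0, 2, size=n_hap)
    anchors = 2 * parents + start
    partners = 2 * parents + 1 - start
    return _recombine(haps, anchors, partners, gaps_p, rng, anchor_site=0)


class _SweepLost(Exception):
    pass


def _draw_trajectory(
    rng: np.random.Generator,
    two_n: int,
    k0: int,
    s: float,
    h: float,
    n_gens: int,
    lo: float,
    hi: float,
    max_tries: int,
) -> np.ndarray:
    """Focal-allele count path under WF selection, conditioned on survival.

    One-locus paths are drawn until one neither dies out nor leaves the
    final-frequency window — microseconds per attempt, so conditioning on
    establishment is essentially free.  The structured simulation is then
    run once, matching these counts generation by generation.
    """
    for _ in range(max_tries):
        n = k0
        traj = np.empty(n_gens, dtype=np.int64)
        ok = True
        for t in range(n_gens):
            p = n / two_n
            het, hom = 1.0 + h * s, 1.0 + s
            num = p * p * hom + p * (1 - p) * het
            den = p * p * hom + 2 * p * (1 - p) * het + (1 - p) ** 2
            n = int(rng.binomial(two_n, num / den))
            if n == 0 or n == two_n:
                ok = False
                break
            traj[t] = n
        if ok and lo <= traj[-1] / two_n <= hi:
            return traj
    raise RuntimeError(
        f"no sweep trajectory satisfied the conditioning in {max_tries} tries"
    )


def _wf_generation_conditioned(
    haps: np.ndarray,
    gaps_p: np.ndarray,
    rng: np.random.Generator,
    focal: int,
    n_target: int,
) -> np.ndarray:
    """One WF generation conditioned on the focal derived count.

    Each offspring haplotype is anchored at the focal site: its anchor
    parent haplotype is drawn uniformly from the required allele class,
    and the recombinant mosaic alternates between the anchor and its
    within-individual partner with crossover parity measured from the
    focal column — so exactly ``n_target`` offspring carry the derived
    allele while linked diversity drifts freely.
    """
    n_hap, n_sites = haps.shape
    focal_col = haps[:, focal]
    der = np.nonzero(focal_col == 1)[0]
    anc = np.nonzero(focal_col == 0)[0]
    if n_target > 0 and der.size == 0:
        raise _SweepLost
    anchors = np.empty(n_hap, dtype=np.int64)
    anchors[:n_target] = rng.choice(der, size=n_target, replace=True)
    anchors[n_target:] = rng.choice(anc, size=n_hap - n_target, replace=True)
    partners = anchors ^ 1
    child = _recombine(haps, anchors, partners, gaps_p, rng, anchor_site=focal)
    return child[rng.permutation(n_hap)]


def _advance(
    state: dict,
    g: int,
    cfg: SimConfig,
    gaps_p: np.ndarray,
    rng: np.random.Generator,
    selection_on: bool,
    skip: str | None = None,
) -> None:
    """Advance all live demes from generation g-1 to g, founding daughters."""
    sweep = cfg.sweep
    pop_names = cfg.pop_names
    split_of = dict(zip(pop_names, cfg.split_schedule))
    sweep_pops = set(sweep.pops or pop_names) if sweep is not None else set()
    for i, name in enumerate(pop_names):
        if split_of[name] == g - 1 and name not in state["pops"]:
            rows = rng.integers(
                0, state["pool"].shape[0], size=2 * cfg.diploid_size[i]
            )
            state["pops"][name] = state["pool"][rows].copy()
    pool_live = any(split_of[p] >= g for p in pop_names)
    if pool_live:
        pool_selected = (
            selection_on and any(split_of[p] >= g for p in sweep_pops)
        )
        state["pool"] = _wf_generation(
            state["pool"], gaps_p, rng,
            sweep.focal_site if (sweep and pool_selected) else None,
            sweep.s if sweep else 0.0, sweep.h if sweep else 0.5,
        )
    for name in state["pops"]:
        if name == skip:
            continue
        selected = (
            selection_on and sweep is not None and name in sweep_pops
        )
        state["pops"][name] = _wf_generation(
            state["pops"][name], gaps_p, rng,
            sweep.focal_site if (sweep and selected) else None,
            sweep.s if sweep else 0.0, sweep.h if sweep else 0.5,
        )


def _focal_alive(state: dict, cfg: SimConfig, g: int) -> bool:
    """Does any copy of the derived focal allele survive where it matters?"""
    sweep = cfg.sweep
    pop_names = cfg.pop_names
    split_of = dict(zip(pop_names, cfg.split_schedule))
    sweep_pops = set(sweep.pops or pop_names)
    total = 0
    if any(split_of[p] >= g for p in sweep_pops):  # pool still feeds a target
        total += int(state["pool"][:, sweep.focal_site].sum())
    for name in sweep_pops & set(state["pops"]):
        total += int(state["pops"][name][:, sweep.focal_site].sum())
    return total > 0


def _finish(state: dict, cfg: SimConfig, rng: np.random.Generator) -> dict:
    """Found any population scheduled to split at the final generation."""
    for i, name in enumerate(cfg.pop_names):
        if name not in state["pops"]:
            rows = rng.integers(
                0, state["pool"].shape[0], size=2 * cfg.diploid_size[i]
            )
            state["pops"][name] = state["pool"][rows].copy()
    return state


def simulate(cfg: SimConfig) -> SimResult:
    """Run the simulator; returns panels, maps, ancestral truth and sweep truth.

    With a conditioned sweep, the post-onset phase is re-drawn from the
    onset checkpoint (fresh spawned RNG stream, the mutation re-introduced)
    whenever the allele is lost or ends outside ``final_freq_range`` in a
    target population, up to ``max_retries`` attempts.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(ss)
    pool_n = cfg.pool_diploid_size or max(cfg.diploid_size)
    n_sites = cfg.n_sites
    sweep = cfg.sweep

    positions = np.sort(
        rng.choice(cfg.chrom_length_bp, size=n_sites, replace=False) + 1
    ).astype(np.int64)
    gaps_p = np.minimum(cfg.recomb_rate * np.diff(positions).astype(float), 0.5)

    a, b = cfg.init_freq_spectrum
    founder_freq = rng.beta(a, b, size=n_sites)
    pool = (rng.random((2 * pool_n, n_sites)) < founder_freq).astype(np.uint8)
    if sweep is not None:
        pool[:, sweep.focal_site] = 0  # monomorphic ancestral until onset
    anc_is_ref = np.where(pool.mean(axis=0) > 0.5, ANC_ALT, ANC_REF).astype(np.int8)

    pop_names = cfg.pop_names
    split_of = dict(zip(pop_names, cfg.split_schedule))
    onset = None
    if sweep is not None:
        onset = (
            sweep.onset_generation
            if sweep.onset_generation is not None
            else min(split_of[p] for p in (sweep.pops or pop_names))
        )

    state = {"pool": pool, "pops": {}}
    pre_end = onset if onset is not None else cfg.n_generations
    for g in range(1, pre_end + 1):
        _advance(state, g, cfg, gaps_p, rng, selection_on=False)

    n_retries = 0
    targets = tuple(sweep.pops or pop_names) if sweep is not None else ()
    trajectory_mode = (
        sweep is not None
        and sweep.condition_on_sweep
        and len(targets) == 1
        and onset >= split_of[targets[0]]
    )
    if trajectory_mode:
        # One-deme sweep: condition on a pre-drawn focal frequency path
        # instead of retrying whole structured runs.
        target = targets[0]
        ti = pop_names.index(target)
        if target not in state["pops"]:
            rows = rng.integers(
                0, state["pool"].shape[0], size=2 * cfg.diploid_size[ti]
            )
            state["pops"][target] = state["pool"][rows].copy()
        two_n = 2 * cfg.diploid_size[ti]
        k_copies = max(1, round(sweep.start_freq * two_n))
        lo, hi = sweep.final_freq_range or (0.0, 1.0)
        rng_traj = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(2, 0))
        )
        traj = _draw_trajectory(
            rng_traj, two_n, k_copies, sweep.s, sweep.h,
            cfg.n_generations - pre_end, lo, hi, max_tries=100_000,
        )
        rng_post = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1, 0))
        )
        carriers = rng_post.choice(two_n, size=k_copies, replace=False)
        state["pops"][target][carriers, sweep.focal_site] = 1
        for t, g in enumerate(range(pre_end + 1, cfg.n_generations + 1)):
            _advance(
                state, g, cfg, gaps_p, rng_post, selection_on=True, skip=target
            )
            state["pops"][target] = _wf_generation_conditioned(
                state["pops"][target], gaps_p, rng_post,
                sweep.focal_site, int(traj[t]),
            )
        state = _finish(state, cfg, rng_post)
    elif sweep is not None:
        checkpoint = {
            "pool": state["pool"].copy(),
            "pops": {k: v.copy() for k, v in state["pops"].items()},
        }
        k_copies = max(1, round(sweep.start_freq * checkpoint["pool"].shape[0]))
        attempt = 0
        while True:
            rng_post = np.random.default_rng(
                np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1, attempt))
            )
            state = {
                "pool": checkpoint["pool"].copy(),
                "pops": {k: v.copy() for k, v in checkpoint["pops"].items()},
            }
            carriers = rng_post.choice(
                state["pool"].shape[0], size=k_copies, replace=False
            )
            state["pool"][carriers, sweep.focal_site] = 1
            try:
                for g in range(pre_end + 1, cfg.n_generations + 1):
                    _advance(state, g, cfg, gaps_p, rng_post, selection_on=True)
                    if not _focal_alive(state, cfg, g):
                        raise _SweepLost
                state = _finish(state, cfg, rng_post)
                if sweep.condition_on_sweep:
                    lo, hi = sweep.final_freq_range or (0.0, 1.0)
                    targets = sweep.pops or tuple(pop_names)
                    freqs = {
                        p: state["pops"][p][:, sweep.focal_site].mean()
                        for p in targets
                    }
                    if not all(0.0 < f < 1.0 and lo <= f <= hi for f in freqs.values()):
                        raise _SweepLost
                break
            except _SweepLost:
                attempt += 1
                n_retries = attempt
                if attempt > sweep.max_retries:
                    raise RuntimeError(
                        f"sweep conditioning failed in {sweep.max_retries} "
                        "attempts; weaken the conditioning or change parameters"
                    ) from None
    else:
        state = _finish(state, cfg, rng)

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_sites)
    refs = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx], dtype=object)
    alts = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx], dtype=object)

    panels, sample_to_pop = {}, {}
    for pi, name in enumerate(pop_names):
        n_samp = cfg.sample_diploid_size[pi]
        if n_samp < cfg.diploid_size[pi]:
            chosen = np.sort(rng.choice(cfg.diploid_size[pi], size=n_samp, replace=False))
            rows = np.empty(2 * n_samp, dtype=np.int64)
            rows[0::2], rows[1::2] = 2 * chosen, 2 * chosen + 1
            state["pops"][name] = state["pops"][name][rows]
        ids = [f"{name}_s{j:04d}" for j in range(n_samp)]
        for s_id in ids:
            sample_to_pop[s_id] = name
        panels[name] = HaplotypePanel(
            chrom=cfg.chrom,
            positions=positions,
            ref=refs,
            alt=alts,
            haplotypes=state["pops"][name],
            sample_ids=ids,
            ancestral_is_ref=anc_is_ref,
            snp_ids=np.array(
                [f"snp{j:06d}" for j in range(n_sites)], dtype=object
            ),
        )
    ancestral = {
        (cfg.chrom, int(p)): (refs[j] if anc_is_ref[j] == ANC_REF else alts[j])
        for j, p in enumerate(positions)
    }
    if sweep is not None:
        dfreq = {
            name: float(panels[name].derived_freq()[sweep.focal_site])
            for name in pop_names
        }
        truth = SweepTruth(
            focal_site=sweep.focal_site,
            focal_position=int(positions[sweep.focal_site]),
            s=sweep.s, h=sweep.h,
            pops=sorted(set(sweep.pops or pop_names)),
            derived_freq=dfreq,
            lost={n: f == 0.0 for n, f in dfreq.items()},
            fixed={n: f == 1.0 for n, f in dfreq.items()},
            seed=cfg.seed, n_retries=n_retries,
        )
    else:
        truth = SweepTruth(
            focal_site=None, focal_position=None, s=0.0, h=0.5, pops=[],
            derived_freq={}, lost={}, fixed={}, seed=cfg.seed,
        )
    return SimResult(
        panels=panels,
        pop_map=PopulationMap(sample_to_pop=sample_to_pop),
        ancestral=ancestral,
        truth=truth,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Named fixtures covering each pipeline stage's needs
# ---------------------------------------------------------------------------

def _scenario_configs(seed: int) -> dict[str, SimConfig]:
    return {
        "neutral_single": SimConfig(
            seed=seed, n_pops=1, diploid_size=250, sample_diploid_size=100,
            split_schedule=(200,), n_generations=260,
            n_sites=1500, chrom_length_bp=3_000_000,
        ),
        "neutral_multi": SimConfig(
            seed=seed, n_pops=3, diploid_size=250, sample_diploid_size=60,
            split_schedule=(120,), n_generations=180,
            n_sites=1200, chrom_length_bp=2_400_000,
        ),
        "sweep_single": SimConfig(
            seed=seed, n_pops=1, diploid_size=500, sample_diploid_size=200,
            split_schedule=(150,), n_generations=240,
            n_sites=5000, chrom_length_bp=10_000_000,
            sweep=SweepConfig(focal_site=2500, s=0.1, h=0.5, start_freq=0.0,
                              pops=("pop1",), final_freq_range=(0.6, 0.9)),
        ),
        "sweep_shared": SimConfig(
            seed=seed, n_pops=3, diploid_size=400, sample_diploid_size=100,
            split_schedule=(185,),
            n_generations=210, n_sites=1500, chrom_length_bp=3_000_000,
            sweep=SweepConfig(focal_site=750, s=0.1, h=0.5, start_freq=0.0,
                              pops=("pop1", "pop2", "pop3"),
                              onset_generation=120,
                              final_freq_range=(0.5, 0.95)),
        ),
        "sweep_private": SimConfig(
            seed=seed, n_pops=3, diploid_size=250, sample_diploid_size=60,
            split_schedule=(150,), n_generations=220,
            n_sites=1500, chrom_length_bp=3_000_000,
            sweep=SweepConfig(focal_site=750, s=0.12, h=0.5, start_freq=0.0,
                              pops=("pop1",), final_freq_range=(0.7, 0.97)),
        ),
        "freqscan_differentiated": SimConfig(
            seed=seed, n_pops=12, diploid_size=120,
            sample_diploid_size=(14, 25) + (15,) * 10,
            split_schedule=(100,), n_generations=170, n_sites=1200,
            chrom_length_bp=2_400_000,
            sweep=SweepConfig(focal_site=600, s=0.15, h=0.5, start_freq=0.0,
                              pops=("pop2",), final_freq_range=(0.25, 0.8)),
        ),
    }


SCENARIOS = tuple(sorted(_scenario_configs(0)))

# the 12-group naming used by the differentiated-frequency fixture; pop2 is
# the selected NWA-like group
_FREQSCAN_GROUPS = (
    "NEE", "NWA", "Slavs", "Europe", "Altaians", "Chukchi", "Tatars",
    "CentralAsia", "Caucasus", "MiddleEast", "India", "Control",
)


def make_fixture(
    scenario: str,
    out_dir: str | Path | None = None,
    seed: int = 0,
    overrides: dict | None = None,
) -> SimResult:
    """Generate a named, seeded fixture; optionally write its file bundle.

    ``overrides`` replaces SimConfig fields (for scaled-down variants).
    With ``out_dir`` the bundle is written: merged phased VCF, population
    map TSV, ancestral TSV, truth JSON, config echo JSON.
    """
    configs = _scenario_configs(seed)
    if scenario not in configs:
        raise ValueError(
            f"unknown scenario {scenario!r}; choose one of {sorted(configs)}"
        )
    cfg = configs[scenario]
    if overrides:
        overrides = dict(overrides)
        # keep the focal site proportionally placed when only the site
        # count is rescaled
        if (
            "n_sites" in overrides
            and "sweep" not in overrides
            and cfg.sweep is not None
        ):
            scale = overrides["n_sites"] / cfg.n_sites
            overrides["sweep"] = dataclasses.replace(
                cfg.sweep, focal_site=int(cfg.sweep.focal_site * scale)
            )
        cfg = dataclasses.replace(cfg, **overrides)
    result = simulate(cfg)
    if scenario == "freqscan_differentiated":
        result.pop_map.pop_to_group.update(
            dict(zip(cfg.pop_names, _FREQSCAN_GROUPS))
        )
        result.pop_map.test_groups = ["NEE", "NWA"]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_phased_vcf(result.merged_panel(), out / "panel.vcf")
        write_population_map(result.pop_map, out / "populations.tsv")
        with open(out / "ancestral.tsv", "w") as fh:
            for (chrom, pos), allele in sorted(
                result.ancestral.items(), key=lambda kv: kv[0][1]
            ):
                fh.write(f"{chrom}\t{pos}\t{allele}\n")
        (out / "truth.json").write_text(result.truth.to_json())
        echo = dataclasses.asdict(cfg)
        (out / "config.json").write_text(json.dumps(echo, indent=1, sort_keys=True))
    return result
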