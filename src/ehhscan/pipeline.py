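"""End-to-end pipeline orchestration.

``run_pipeline`` executes the stages qc -> ihs -> xpehh -> windows ->
freqscan -> report over either a simulated fixture or user-supplied
inputs, writing one TSV per product plus a run log recording versions,
seeds and thresholds.  Outputs are deterministic under a fixed seed:
column order and float formatting are pinned.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .ehh import ehh_profile, profiles_to_frame
from .freqscan import ScanConfig, dosage_table, genome_scan
from .genes import GeneModel, annotate
from .ihs import coincidence, ihs_scan, significant_snps, standardize
from .panel import (
    PopulationMap, QCThresholds, load_phased_vcf, polarize, qc_filter,
    read_ancestral_tsv, read_population_map,
)
from .simulate import make_fixture
from .windows import cross_population_windows, window_outliers
from .xpehh import pattern_matrix, significant_xpehh, xpehh_scan

log = logging.getLogger(__name__)

ALL_STAGES = ("qc", "ihs", "xpehh", "windows", "freqscan", "report")
_FLOAT_FMT = "%.6g"


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        if str(config).endswith((".yaml", ".yml")):
            import yaml

            return yaml.safe_load(text)
        return json.loads(text)
    return dict(config)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


class PipelineInputError(FileNotFoundError):
    """A stage's required input is missing."""


def _gather_panel(cfg: dict, out_dir: Path, seed: int):
    """One merged multi-population panel plus the population map."""
    if "simulate" in cfg:
        sim_cfg = cfg["simulate"]
        result = make_fixture(
            sim_cfg["scenario"],
            out_dir=out_dir / "fixture",
            seed=sim_cfg.get("seed", seed),
            overrides=sim_cfg.get("overrides"),
        )
        return result.merged_panel(), result.pop_map
    inputs = cfg.get("inputs")
    if not inputs:
        raise PipelineInputError("stage qc: neither 'simulate' nor 'inputs' configured")
    for key in ("vcf", "population_map"):
        if key not in inputs or not Path(inputs[key]).exists():
            raise PipelineInputError(f"stage qc: missing input '{key}'")
    panel = load_phased_vcf(inputs["vcf"])
    pop_map = read_population_map(
        inputs["population_map"],
        test_groups=cfg.get("test_groups"),
        reference_populations=cfg.get("reference_populations"),
    )
    if "ancestral" in inputs:
        panel = polarize(panel, read_ancestral_tsv(inputs["ancestral"]))
    pop_map.validate_panel(panel)
    return panel, pop_map


def run_pipeline(config) -> dict:
    """Run the configured stages; returns a dict of written output paths.

    The config (dict, or path to YAML/JSON) names inputs or a simulation
    scenario, the stage list, thresholds and the seed.  A missing input
    fails fast with the stage named.
    """
    cfg = _load_config(config)
    out_dir = Path(cfg.get("out_dir", "pipeline_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = list(cfg.get("stages", ALL_STAGES))
    p_threshold = float(cfg.get("p_threshold", 1e-5))
    outputs: dict[str, str] = {}
    from importlib.metadata import version as _dist_version

    try:
        pkg_version = _dist_version("ehhscan")
    except Exception:
        pkg_version = "unknown"
    log_lines = [
        f"ehhscan {pkg_version}",
        f"numpy {np.__version__}, pandas {pd.__version__}",
        f"seed {seed}",
        f"stages {stages}",
        f"p_threshold {p_threshold}",
    ]

    merged, pop_map = _gather_panel(cfg, out_dir, seed)
    if cfg.get("reference_populations"):
        pop_map.reference_populations = list(cfg["reference_populations"])
    if cfg.get("test_groups"):
        pop_map.test_groups = list(cfg["test_groups"])
    scan_pops = cfg.get("populations") or sorted(
        set(pop_map.populations) - set(pop_map.reference_populations)
    )

    if "qc" in stages:
        # QC on the combined panel (the shared-SNP framing): MAF and missing
        # rate over everyone, exact HWE within each population
        thr = QCThresholds(**cfg.get("qc_thresholds", {}))
        log_lines.append(f"qc_thresholds {dataclasses.asdict(thr)}")
        merged, report = qc_filter(merged, thr, pop_map=pop_map)
        _write(report.to_frame(), out_dir / "qc_report.tsv")
        outputs["qc_report"] = str(out_dir / "qc_report.tsv")
        from .panel import write_phased_vcf

        write_phased_vcf(merged, out_dir / "filtered.vcf")
        outputs["filtered_vcf"] = str(out_dir / "filtered.vcf")
    qc_panels = {
        pop: merged.take_samples(pop_map.sample_indices(merged, pop))
        for pop in pop_map.populations
    }

    tables = {}
    if "ihs" in stages:
        for pop in scan_pops:
            raw = ihs_scan(qc_panels[pop])
            tables[pop] = standardize(raw)
            _write(tables[pop].frame, out_dir / f"ihs_{pop}.tsv")
            outputs[f"ihs_{pop}"] = str(out_dir / f"ihs_{pop}.tsv")
        shared = coincidence(tables, p_threshold=p_threshold)
        _write(shared, out_dir / "ihs_shared.tsv")
        outputs["ihs_shared"] = str(out_dir / "ihs_shared.tsv")

    xp_results = {}
    if "xpehh" in stages:
        refs = pop_map.reference_populations or []
        for pop in scan_pops:
            for ref in refs:
                res = xpehh_scan(
                    qc_panels[pop], qc_panels[ref],
                    test_label=pop, reference_label=ref,
                )
                xp_results[(pop, ref)] = res
                _write(res.frame, out_dir / f"xpehh_{pop}_vs_{ref}.tsv")
                outputs[f"xpehh_{pop}_vs_{ref}"] = str(
                    out_dir / f"xpehh_{pop}_vs_{ref}.tsv"
                )
        if xp_results:
            grid = pattern_matrix(xp_results, p_threshold=p_threshold)
            _write(grid, out_dir / "xpehh_pattern_matrix.tsv")
            outputs["xpehh_pattern_matrix"] = str(out_dir / "xpehh_pattern_matrix.tsv")

    if "windows" in stages and tables:
        win_results = {
            pop: window_outliers(t.frame) for pop, t in tables.items()
        }
        for pop, res in win_results.items():
            _write(res.frame, out_dir / f"windows_{pop}.tsv")
            outputs[f"windows_{pop}"] = str(out_dir / f"windows_{pop}.tsv")
        shared_w = cross_population_windows(win_results)
        _write(shared_w, out_dir / "windows_shared.tsv")
        outputs["windows_shared"] = str(out_dir / "windows_shared.tsv")

    if "freqscan" in stages:
        dosages = dosage_table(merged)
        signals = []
        for pop, t in tables.items():
            sig = t.frame[t.frame["neglog10_p"] >= 4.0]  # iHS p < 1e-4 support set
            signals.append(sig[["chrom", "pos"]])
        for res in xp_results.values():
            sig = significant_xpehh(res, p_threshold)
            signals.append(sig[["chrom", "pos"]])
        ehh_signals = (
            pd.concat(signals, ignore_index=True).drop_duplicates()
            if signals
            else pd.DataFrame(columns=["chrom", "pos"])
        )
        scan_cfg = ScanConfig(
            mode="genome", seed=seed, **cfg.get("freqscan", {})
        )
        log_lines.append(f"freqscan {dataclasses.asdict(scan_cfg)}")
        fs = genome_scan(dosages, ehh_signals, pop_map, scan_cfg)
        _write(fs.snp_frame, out_dir / "freqscan_snps.tsv")
        _write(fs.locus_frame, out_dir / "freqscan_loci.tsv")
        outputs["freqscan_snps"] = str(out_dir / "freqscan_snps.tsv")
        outputs["freqscan_loci"] = str(out_dir / "freqscan_loci.tsv")

    if "report" in stages and tables:
        genes = (
            GeneModel.from_bed(cfg["inputs"]["genes_bed"])
            if cfg.get("inputs", {}).get("genes_bed")
            else None
        )
        shared = coincidence(tables, p_threshold=p_threshold)
        table1 = annotate(shared, genes) if len(shared) else shared
        _write(table1, out_dir / "report_shared_snps.tsv")
        outputs["report_shared_snps"] = str(out_dir / "report_shared_snps.tsv")
        # EHH decay profile data at the top shared hit (or top single hit)
        top = None
        if len(shared):
            top = (str(shared.iloc[0]["chrom"]), int(shared.iloc[0]["pos"]))
        else:
            for pop, t in tables.items():
                sig = significant_snps(t, p_threshold)
                if len(sig):
                    best = sig.loc[sig["ihs"].abs().idxmax()]
                    top = (str(best["chrom"]), int(best["pos"]))
                    break
        if top is not None:
            profs = []
            for pop in scan_pops:
                panel = qc_panels[pop]
                try:
                    j = panel.site_index(top[1])
                except KeyError:
                    continue
                for cls in ("ancestral", "derived"):
                    try:
                        left, right = ehh_profile(panel, j, cls)
                    except ValueError:
                        continue
                    df = profiles_to_frame([left, right])
                    df.insert(0, "population", pop)
                    profs.append(df)
            if profs:
                _write(pd.concat(profs, ignore_index=True), out_dir / "report_ehh_decay.tsv")
                outputs["report_ehh_decay"] = str(out_dir / "report_ehh_decay.tsv")

    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    outputs["run_log"] = str(out_dir / "run_log.txt")
    return outputs
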