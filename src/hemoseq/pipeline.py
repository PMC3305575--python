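"""End-to-end orchestration of the resequencing analysis on one config.

Runs simulate -> demux -> readfilter -> call -> matrix -> assoc -> burden ->
replicate -> annotate -> reports, writing every stage's outputs plus a run
manifest (parameters, per-stage record counts, conservation checks) into a
run directory.  Reruns with an identical config are byte-identical: every
random stream derives from the single configured seed.

Replication is simulated at genotype level (the analogue of targeted PCR +
Sanger genotyping of the carried-over sites): stage-1 and stage-2 cohorts
are drawn from the truth allele frequencies of the selected sites, with
sites lacking a truth record (false positives) drawn as null at their
observed discovery frequency.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import annotate_variants, flag_novelty, frequency_spectrum
from .association import ScreenConfig, results_table, screen
from .burden import burden_report, burden_test
from .calling import CallParams, call_sample, calls_frame, write_vcf
from .concordance import agreement_report, callset_overlap, genotype_agreement
from .gmatrix import build_matrix, write_matrix_vcf, write_ped_map
from .panel import build_panel
from .reads import (BarcodeManifest, assign_barcodes, demux_report,
                    process_sample_reads, write_reads)
from .replication import StageConfig, combined_analysis, select_for_stage2
from .sim import SimConfig, case_frequency, simulate_genotypes, simulate_reads

GENOME_BP = 3_000_000_000  # human genome scale used for enrichment bookkeeping
_STREAM_REPLICATION = 7


def compute_enrichment(on_target_reads: int, total_reads: int, target_bp: int, genome_bp: int = GENOME_BP) -> float:
    """Capture enrichment: on-target read fraction over the target's genome share."""
    if min(on_target_reads, total_reads, target_bp, genome_bp) <= 0 or total_reads < on_target_reads:
        raise ValueError("counts/sizes must be positive with on_target <= total")
    return (on_target_reads / total_reads) / (target_bp / genome_bp)


@dataclass
class RunConfig:
    outdir: str = "hemoseq_run"
    seed: int = 0
    panel: dict = field(default_factory=lambda: {"n_genes": 10, "exons_per_gene": 3})
    cohort: dict = field(default_factory=dict)  # SimConfig overrides
    readfilter: dict = field(default_factory=lambda: {"min_mapq": 50, "with_strand_dups": False})
    calling: dict = field(default_factory=dict)  # CallParams overrides
    matrix: dict = field(default_factory=lambda: {"min_ref_depth": 10})
    assoc: dict = field(default_factory=dict)  # ScreenConfig overrides
    burden: dict = field(default_factory=dict)  # consequence filter overrides
    replication: dict = field(default_factory=dict)  # StageConfig overrides
    max_mismatch: int = 1
    genome_bp: int = GENOME_BP

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained for debugging."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "hemoseq",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items() if k not in ("outdir",)
        },
        "stages": [],
    }
    state: dict = {}

    stages = [
        ("simulate", _stage_simulate),
        ("demux", _stage_demux),
        ("readfilter", _stage_readfilter),
        ("call", _stage_call),
        ("matrix", _stage_matrix),
        ("assoc", _stage_assoc),
        ("burden", _stage_burden),
        ("replicate", _stage_replicate),
        ("annotate", _stage_annotate),
        ("reports", _stage_reports),
    ]
    for name, fn in stages:
        try:
            record = fn(config, state, outdir)
        except Exception as exc:  # noqa: BLE001 - stage name + cause surfaced
            _write_manifest(manifest, outdir)
            raise StageError(name, exc) from exc
        record["stage"] = name
        manifest["stages"].append(record)
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _stage_simulate(config: RunConfig, state: dict, outdir: Path) -> dict:
    panel = build_panel(seed=config.seed, **config.panel)
    sim_config = SimConfig(seed=config.seed, **config.cohort)
    truth = simulate_genotypes(panel, sim_config)
    reads, stats = simulate_reads(panel, truth, sim_config)
    state.update(panel=panel, sim_config=sim_config, truth=truth, reads=reads, read_stats=stats)
    panel.write(outdir)
    truth.write(outdir)
    write_reads(reads, outdir / "reads.tsv")
    return {
        "n_sites_truth": len(truth.sites),
        "n_samples": len(truth.samples),
        "on_target_reads": stats.on_target_reads,
        "off_target_reads": stats.off_target_reads,
        "target_bp": panel.target_bp,
    }


def _stage_demux(config: RunConfig, state: dict, outdir: Path) -> dict:
    manifest_bc = BarcodeManifest.from_truth(state["truth"], config.max_mismatch)
    assigned, unassigned = assign_barcodes(state["reads"], manifest_bc)
    if len(assigned) + unassigned != len(state["reads"]):
        raise AssertionError("demux conservation violated")
    state["assigned"] = assigned
    demux_report(assigned, manifest_bc, unassigned).to_csv(
        outdir / "demux_report.tsv", sep="\t", index=False
    )
    return {"n_in": len(state["reads"]), "n_assigned": len(assigned), "n_unassigned": unassigned}


def _stage_readfilter(config: RunConfig, state: dict, outdir: Path) -> dict:
    per_sample: dict[str, pd.DataFrame] = {}
    n_out = 0
    for sample, grp in state["assigned"].groupby("sample"):
        kept = process_sample_reads(
            grp,
            min_mapq=config.readfilter.get("min_mapq", 50),
            with_strand_dups=config.readfilter.get("with_strand_dups", False),
        )
        per_sample[sample] = kept
        n_out += len(kept)
    state["filtered"] = per_sample
    return {"n_in": len(state["assigned"]), "n_out": n_out}


def _stage_call(config: RunConfig, state: dict, outdir: Path) -> dict:
    params = CallParams(**config.calling)
    callsets = {
        sample: call_sample(reads, state["panel"], sample, params)
        for sample, reads in state["filtered"].items()
    }
    state["callsets"] = callsets
    state["call_params"] = params
    vcf_dir = outdir / "calls"
    vcf_dir.mkdir(exist_ok=True)
    n_pass = n_fail = 0
    for sample, cs in callsets.items():
        write_vcf(cs, state["panel"], vcf_dir / f"{sample}.vcf")
        n_pass += len(cs.passing())
        n_fail += len(cs.calls) - len(cs.passing())
    calls_frame(callsets).to_csv(outdir / "calls.tsv", sep="\t", index=False)
    return {"n_candidate_calls": n_pass + n_fail, "n_pass": n_pass, "n_fail": n_fail}


def _stage_matrix(config: RunConfig, state: dict, outdir: Path) -> dict:
    phenos = state["truth"].samples[["sample", "phenotype"]]
    matrix = build_matrix(
        state["callsets"], phenos, min_ref_depth=config.matrix.get("min_ref_depth", 10)
    )
    state["matrix"] = matrix
    write_ped_map(matrix, outdir / "cohort")
    write_matrix_vcf(
        matrix, outdir / "cohort.vcf",
        {c: len(s) for c, s in state["panel"].reference.items()},
    )
    counts = {
        "homref": int((matrix.genotypes == 0).sum()),
        "het": int((matrix.genotypes == 1).sum()),
        "homvar": int((matrix.genotypes == 2).sum()),
        "missing": int((matrix.genotypes == -1).sum()),
    }
    if sum(counts.values()) != matrix.genotypes.size:
        raise AssertionError("genotype count conservation violated")
    return {
        "n_sites": len(matrix.sites),
        "n_samples": matrix.n_samples,
        "genotyping_success": matrix.genotyping_success(),
        "genotype_counts": counts,
    }


def _stage_assoc(config: RunConfig, state: dict, outdir: Path) -> dict:
    cfg = ScreenConfig(**config.assoc)
    ranked, top = screen(state["matrix"], cfg)
    state["ranked"], state["top"], state["screen_config"] = ranked, top, cfg
    results_table(ranked).to_csv(outdir / "assoc_results.tsv", sep="\t", index=False)
    results_table(top).to_csv(outdir / "assoc_top.tsv", sep="\t", index=False)
    return {"n_tested": len(ranked), "n_selected": len(top)}


def _stage_annotate(config: RunConfig, state: dict, outdir: Path) -> dict:
    matrix = state["matrix"]
    variants = matrix.sites.copy()
    variants["var_type"] = np.where(variants["alt"] == "-", "deletion", "SNV")
    ann = annotate_variants(variants, state["panel"])
    # the simulated "database" of known variation holds the common variants
    # (as dbSNP-like catalogues do); rare/burden sites count as novel
    truth_sites = state["truth"].sites
    known = truth_sites.loc[
        truth_sites["site_class"].isin(["background_common", "risk"]),
        ["contig", "pos", "ref", "alt"],
    ]
    ann["known"], _ = flag_novelty(ann, [known])
    state["annotations"] = ann
    ann.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    stats_df = matrix.minor_allele_stats()
    spectrum = frequency_spectrum(stats_df["maf"], stats_df["minor_count"], ann["consequence"])
    spectrum.to_csv(outdir / "spectrum.tsv", sep="\t")
    state["spectrum"] = spectrum
    return {"n_annotated": len(ann), "n_known": int(ann["known"].sum())}


def _stage_burden(config: RunConfig, state: dict, outdir: Path) -> dict:
    # burden needs annotations; compute them on demand (annotate stage re-uses)
    if "annotations" not in state:
        _stage_annotate(config, state, outdir)
    results = burden_test(
        state["matrix"],
        state["annotations"],
        state["panel"].gene_sets,
        damaging_only=config.burden.get("damaging_only", False),
    )
    state["burden"] = results
    burden_report(results).to_csv(outdir / "burden.tsv", sep="\t", index=False)
    return {name.gene_set: {"t_case": name.t_case, "t_control": name.t_control, "p": name.p}
            for name in results}


def _stage_replicate(config: RunConfig, state: dict, outdir: Path) -> dict:
    cfg = StageConfig(**config.replication)
    cfg.validate()
    rng = np.random.default_rng([config.seed, _STREAM_REPLICATION])
    truth_sites = state["truth"].sites
    truth_by_key = {
        f"{r.contig}:{r.pos}:{r.ref}:{r.alt}": r for r in truth_sites.itertuples(index=False)
    }
    top = state["top"]
    rows = []
    for res in top.itertuples(index=False):
        tr = truth_by_key.get(res.site_id)
        if tr is not None:
            f_case, f_ctrl = float(tr.case_maf), float(tr.control_maf)
        else:  # false-positive site: replicate as null at the observed frequency
            f_case = f_ctrl = max(res.maf_pooled, 1e-4)
        n1_cases = cfg.stage1_n // 2
        n1_ctrls = cfg.stage1_n - n1_cases
        t1 = _draw_allele_table(rng, f_case, f_ctrl, n1_cases, n1_ctrls)
        freq1_case = t1[0][0] / (2 * n1_cases)
        freq1_ctrl = t1[1][0] / (2 * n1_ctrls)
        selectable = 0 < freq1_case < 1 and 0 < freq1_ctrl < 1
        if selectable:
            sel = select_for_stage2([(res.site_id, freq1_case, freq1_ctrl)], cfg)[0]
        else:  # stage-1 frequency degenerate: cannot project power, stop here
            sel = {"power": 0.0, "selected": False}
        if sel["selected"]:
            t2 = _draw_allele_table(
                rng, f_case, f_ctrl, cfg.full_n_cases - n1_cases, cfg.full_n_controls - n1_ctrls
            )
            combined = combined_analysis(t1, t2)
        else:
            combined = combined_analysis(t1, None)
        rows.append(
            {
                "site": res.site_id,
                "discovery_p": res.p,
                "stage1_case_freq": freq1_case,
                "stage1_control_freq": freq1_ctrl,
                "power": sel["power"],
                "selected": bool(sel["selected"]),
                "combined_p": combined["p"],
                "combined_or": combined["odds_ratio"],
                "ci_low": combined["ci_low"],
                "ci_high": combined["ci_high"],
            }
        )
    report = pd.DataFrame(rows)
    state["replication"] = report
    report.to_csv(outdir / "replication.tsv", sep="\t", index=False)
    return {"n_carried": len(rows), "n_selected_stage2": int(report["selected"].sum()) if len(report) else 0}


def _draw_allele_table(rng, f_case, f_ctrl, n_cases, n_ctrls):
    a = int(rng.binomial(2 * n_cases, f_case))
    c = int(rng.binomial(2 * n_ctrls, f_ctrl))
    return [[a, 2 * n_cases - a], [c, 2 * n_ctrls - c]]


def _stage_reports(config: RunConfig, state: dict, outdir: Path) -> dict:
    stats = state["read_stats"]
    enrichment = compute_enrichment(
        stats.on_target_reads, stats.total_reads, state["panel"].target_bp, config.genome_bp
    )
    summary = {
        "on_target_fraction": stats.on_target_reads / stats.total_reads,
        "enrichment_fold": enrichment,
        "mean_depth": _mean_target_depth(state),
        "genotyping_success": state["matrix"].genotyping_success(),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def _mean_target_depth(state) -> float:
    total = n = 0
    for cs in state["callsets"].values():
        for arr in cs.depth.values():
            total += int(arr.sum())
            n += len(arr)
    return total / n if n else 0.0
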