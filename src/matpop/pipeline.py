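"""Orchestration: wire the analysis stages together with a single config,
deterministic seeds, and a machine-readable run manifest.

Stage order: stats -> ld-sr -> dstat -> isolation-test -> sweep-fit ->
codon-load.  Each stage writes its own outputs into the run directory and
never mutates another stage's outputs; the manifest records the resolved
config, its hash, the seed, and a digest of every file written, so two
runs with the same config and seed produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import codon_load, introgression, ld_sr, popgen_stats, sweep_fit
from .coalescent_sim import MSCParams
from .io_formats import (
    CallabilityMask,
    Region,
    VariantTable,
    make_windows,
    read_cds_alignments,
    read_sample_sheet,
    read_vcf,
    write_regions_bed,
    write_stats_tsv,
)
from .synthetic_data import StudyConfig, simulate_study

logger = logging.getLogger(__name__)

ALL_STAGES = ("stats", "ld-sr", "dstat", "isolation-test", "sweep-fit",
              "codon-load")


class PipelineError(RuntimeError):
    """A stage failed or lacked its inputs; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run.

    Defaults are the analysis constants used throughout the package:
    100-kb windows with a 20-kb step, 25-kb divergence windows, a 10%
    called-site threshold, the 95% autosomal LD quantile, 250-kb jackknife
    blocks, 50,000 isolation loci, and 25,000 sweep replicates with a 5%
    acceptance tolerance.
    """

    outdir: str = "matpop_run"
    vcf: str | None = None
    sample_sheet: str | None = None
    simulate: dict | None = None  # StudyConfig fields; overrides vcf input
    lineage: str | None = None
    mat_chrom: str = "mat"
    mat_locus_pos: int | None = None
    donor: str | None = None
    outgroup: str | None = None
    cds_dir: str | None = None
    optimal_codon_tsv: str | None = None
    msc: dict | None = None  # MSCParams fields for the isolation test
    window_size: int = 100_000
    step: int = 20_000
    dxy_window: int = 25_000
    min_called_frac: float = 0.10
    ld_quantile: float = 0.95
    gap_max: int = 2
    jackknife_block: int = 250_000
    isolation_loci: int = 50_000
    sweep_reps: int = 25_000
    sweep_tol: float = 0.05
    sweep_theta0_grid: list | None = None
    sweep_ts_grid: list | None = None
    stages: tuple = ALL_STAGES
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(config: RunConfig) -> str:
    d = config.to_dict()
    d.pop("outdir", None)  # hash the analysis config, not its location
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class _RunState:
    table: VariantTable
    mask: CallabilityMask
    focal: list
    mat_A: list
    mat_a: list
    one_per_het: list
    outputs: list = field(default_factory=list)
    sr_region: Region | None = None


def _load_inputs(config: RunConfig, outdir: Path) -> _RunState:
    if config.simulate is not None:
        study_cfg = StudyConfig(**{**config.simulate, "seed": config.seed})
        study = simulate_study(study_cfg)
        inputs = outdir / "inputs"
        study.write(inputs)
        table = study.table
        config.mat_chrom = study_cfg.mat_chrom
        if config.mat_locus_pos is None:
            config.mat_locus_pos = study_cfg.mat_locus_pos
        if config.lineage is None:
            config.lineage = study_cfg.lineage
        if config.donor is None and study_cfg.introgression is not None:
            config.donor = study_cfg.introgression.donor
        if config.donor is None and "donor" in study_cfg.species_divergence:
            config.donor = "donor"
        if config.outgroup is None:
            tau = study_cfg.species_divergence
            config.outgroup = max(tau, key=tau.get)
        lengths = study_cfg.chrom_lengths
    elif config.vcf is not None:
        table = read_vcf(config.vcf, config.sample_sheet)
        lengths = {c: int(table.pos[table.sites_in(c)].max()) + 1
                   for c in table.chroms}
    else:
        raise PipelineError("stats", "no input: give vcf or simulate")
    mask = CallabilityMask.all_callable(lengths)
    if config.lineage is None:
        lineages = [s.lineage for s in table.samples if s.lineage]
        config.lineage = max(set(lineages), key=lineages.count) \
            if lineages else ""
    focal = [s for s in table.samples if s.lineage == config.lineage]
    mat_A = [s.sample_id for s in focal if s.mating_type == "A"]
    mat_a = [s.sample_id for s in focal if s.mating_type == "a"]
    return _RunState(
        table=table, mask=mask, focal=[s.sample_id for s in focal],
        mat_A=mat_A, mat_a=mat_a,
        one_per_het=popgen_stats.one_per_heterokaryon(focal),
    )


def _write(state: _RunState, path: Path, writer) -> None:
    writer(path)
    state.outputs.append(path)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the output directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state = _load_inputs(config, outdir)
    completed = []
    for stage in config.stages:
        if stage not in ALL_STAGES:
            raise PipelineError(stage, "unknown stage")
        _STAGE_FUNCS[stage](config, state, outdir)
        completed.append(stage)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "stages_completed": completed,
        "outputs": {str(p.relative_to(outdir)): _file_digest(p)
                    for p in sorted(state.outputs)},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_stats(config: RunConfig, state: _RunState, outdir: Path) -> None:
    samples = state.one_per_het
    if len(samples) < 2:
        raise PipelineError("stats", "need >= 2 focal samples")
    kw = dict(mask=state.mask, window_size=config.window_size,
              step=config.step, min_called_frac=config.min_called_frac)
    pi = popgen_stats.nucleotide_diversity(state.table, samples, **kw)
    _write(state, outdir / "stats_pi.tsv",
           lambda p: write_stats_tsv(pi, p))
    td = popgen_stats.tajimas_d_windows(state.table, samples, **kw)
    _write(state, outdir / "stats_tajimas_d.tsv",
           lambda p: write_stats_tsv(td, p))
    if config.outgroup:
        h = popgen_stats.fay_wu_h_windows(state.table, samples,
                                          config.outgroup, **kw)
        _write(state, outdir / "stats_fay_wu_h.tsv",
               lambda p: write_stats_tsv(h, p))


def _stage_ld_sr(config: RunConfig, state: _RunState, outdir: Path) -> None:
    if config.mat_locus_pos is None:
        raise PipelineError("ld-sr", "mat_locus_pos is required")
    table = state.table
    rows = ld_sr.window_mean_r2(
        table, state.focal, mask=state.mask,
        window_size=config.window_size, step=config.step)
    mat_rows = [r for r in rows if r.region.chrom == config.mat_chrom]
    auto_rows = [r for r in rows if r.region.chrom != config.mat_chrom]
    if not auto_rows:
        raise PipelineError("ld-sr", "no autosomal windows for the cutoff")
    df = pd.DataFrame([{
        "chrom": r.region.chrom, "start": r.region.start,
        "end": r.region.end, "mean_r2": r.mean_r2, "n_pairs": r.n_pairs,
    } for r in rows])
    _write(state, outdir / "ld_windows.tsv",
           lambda p: df.to_csv(p, sep="\t", index=False,
                               float_format="%.10g"))
    sr = ld_sr.detect_sr(mat_rows, auto_rows, config.mat_locus_pos,
                         q=config.ld_quantile, gap_max=config.gap_max,
                         table=table, samples=state.focal)
    regions = [] if sr.empty else [dataclasses.replace(
        sr.region, label=f"SR;method={sr.method};cutoff={sr.cutoff_value:.6g}")]
    _write(state, outdir / "sr_region.bed",
           lambda p: write_regions_bed(regions, p))
    state.sr_region = sr.region


def _stage_dstat(config: RunConfig, state: _RunState, outdir: Path) -> None:
    if not (config.donor and config.outgroup and state.mat_A
            and state.mat_a):
        raise PipelineError("dstat", "donor, outgroup and both mat classes "
                                     "are required")
    res = introgression.d_statistic(
        state.table, state.mat_a[0], state.mat_A[0], config.donor,
        config.outgroup, block_size=config.jackknife_block)
    df = pd.DataFrame([{
        "P1": state.mat_a[0], "P2": state.mat_A[0], "P3": config.donor,
        "outgroup": config.outgroup, "D": res.d, "SE": res.se, "Z": res.z,
        "p": res.p, "n_blocks": res.n_blocks, "ABBA": res.n_abba,
        "BABA": res.n_baba,
    }])
    _write(state, outdir / "dstat.tsv",
           lambda p: df.to_csv(p, sep="\t", index=False,
                               float_format="%.10g"))


def _sr_divergence_median(config, state, sample, other) -> tuple[float, float]:
    """Median 25-kb JC divergence of `sample` vs `other` inside and outside
    the SR on the mat chromosome."""
    sr = state.sr_region
    length = max(int(state.table.pos[state.table.sites_in(
        config.mat_chrom)].max()) + 1, sr.end)
    windows = make_windows(config.mat_chrom, length, config.dxy_window)
    rows = popgen_stats.pairwise_divergence(
        state.table, sample, other, windows=windows, mask=state.mask,
        min_called_frac=config.min_called_frac)
    inside = [r.value for r in rows if r.defined
              and sr.start <= r.region.start and r.region.end <= sr.end]
    outside = [r.value for r in rows if r.defined
               and (r.region.end <= sr.start or r.region.start >= sr.end)]
    if not inside or not outside:
        raise PipelineError("isolation-test",
                            "no defined divergence windows in/out of the SR")
    return float(np.median(inside)), float(np.median(outside))


def _stage_isolation(config: RunConfig, state: _RunState,
                     outdir: Path) -> None:
    if config.msc is None:
        raise PipelineError("isolation-test", "msc parameters are required")
    if config.donor is None:
        raise PipelineError("isolation-test", "donor species is required")
    if state.sr_region is None:
        raise PipelineError("isolation-test",
                            "run ld-sr first to define the SR region")
    focal = state.mat_A[0] if state.mat_A else state.focal[0]
    med_sr, med_r = _sr_divergence_median(config, state, focal, config.donor)
    direction = "lower" if med_sr < med_r else "upper"
    res = introgression.isolation_divergence_test(
        med_sr, MSCParams(**config.msc), n_loci=config.isolation_loci,
        direction=direction, seed=config.seed)
    out = {
        "observed_median_sr": med_sr, "observed_median_r": med_r,
        "direction": direction, "p": res.p, "p_report": res.p_str,
        "n_loci": res.n_loci,
    }
    _write(state, outdir / "isolation_test.json",
           lambda p: Path(p).write_text(json.dumps(out, indent=2)))


def _stage_sweep_fit(config: RunConfig, state: _RunState,
                     outdir: Path) -> None:
    if state.sr_region is None:
        raise PipelineError("sweep-fit",
                            "run ld-sr first to define the SR region")
    samples = state.mat_A if len(state.mat_A) >= 2 else state.focal
    sr = state.sr_region
    sl = state.table.sites_in(config.mat_chrom, sr.start, sr.end)
    idx = state.table.sample_index(samples)
    g = state.table.genotypes[idx, sl]
    obs = sweep_fit.summary_from_genotypes(g, label="SR")
    if obs.s_obs == 0:
        raise PipelineError("sweep-fit", "no segregating sites in the SR")
    res = sweep_fit.fit_sweep_grid(
        obs, theta0_grid=config.sweep_theta0_grid,
        ts_grid=config.sweep_ts_grid, reps=config.sweep_reps,
        tol=config.sweep_tol, seed=config.seed)
    df = res.to_frame()
    _write(state, outdir / "sweep_surface.tsv",
           lambda p: df.to_csv(p, sep="\t", index=False,
                               float_format="%.10g"))
    summary = {
        "S_obs": obs.s_obs, "k_obs": obs.k_obs, "n": obs.n,
        "mle": res.mle, "model_incompatible": res.model_incompatible,
        "n_compatible": len(res.compatible), **res.metadata,
    }
    _write(state, outdir / "sweep_fit.json",
           lambda p: Path(p).write_text(json.dumps(summary, indent=2)))


def _stage_codon_load(config: RunConfig, state: _RunState,
                      outdir: Path) -> None:
    if config.cds_dir is None or config.optimal_codon_tsv is None:
        raise PipelineError("codon-load",
                            "cds_dir and optimal_codon_tsv are required")
    alignments = read_cds_alignments(config.cds_dir)
    table = codon_load.OptimalCodonTable.from_tsv(config.optimal_codon_tsv)
    alignments = codon_load.filter_genes(alignments)
    total = codon_load.SwitchCounts()
    for aln in alignments:
        total = total + codon_load.classify_codon_switches(aln, table)
    genomes = sorted(total.counts)
    _write(state, outdir / "codon_switches.tsv",
           lambda p: total.to_frame().to_csv(p, sep="\t", index=False))
    if len(genomes) == 2:
        cmp = codon_load.compare_switches(total, genomes[0], genomes[1])
        out = {"genomes": genomes, "odds_ratio": cmp.odds_ratio,
               "p": cmp.p, "table": cmp.table}
        _write(state, outdir / "codon_switch_test.json",
               lambda p: Path(p).write_text(json.dumps(out, indent=2)))


_STAGE_FUNCS = {
    "stats": _stage_stats,
    "ld-sr": _stage_ld_sr,
    "dstat": _stage_dstat,
    "isolation-test": _stage_isolation,
    "sweep-fit": _stage_sweep_fit,
    "codon-load": _stage_codon_load,
}
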