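"""Run orchestration: configuration, per-stage RNG streams, staged outputs.

A run is described by a structured config (YAML on disk, a dict in
memory).  Exactly one read source is configured: a ``simulate`` block
(parameters of :class:`~nickseq.simulate.SimulationConfig`) or an
``input`` block naming a FASTQ pair.  Background category fractions may
be given directly or measured from an uncut-control FASTQ pair.

Each stochastic stage draws from its own RNG stream derived from the
master seed and the stage name, so changing one stage's parameters never
perturbs another stage's draws.  All outputs are deterministic under a
fixed seed, and every run writes a manifest recording the config hash,
seed, and package version.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path

import numpy as np
import yaml

from . import __version__, io
from .amplicon import AmpliconSpec, ScoringWindow, TargetSite, locate_cut_site, scoring_window
from .calling import CallRules, call_library
from .consensus import consensus_pipeline, default_layout
from .profiler import (
    asymmetry_index,
    condition_summary,
    coverage,
    CoverageInputs,
    deletion_length_histogram,
    fractional_decrease_map,
    insertion_length_histogram,
    snv_spectrum_map,
)
from .simulate import (
    DonorEdit,
    SimulationConfig,
    check_geometry,
    default_amplicon,
    default_site,
    render_reads,
    simulate_library,
)

__all__ = ["RunConfig", "load_config", "rng_for", "run_all", "run_simulate",
           "run_consensus", "run_call", "run_profile"]


def rng_for(seed: int, stage: str) -> np.random.Generator:
    """Independent RNG stream for one pipeline stage."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(stage.encode())]))


@dataclasses.dataclass
class RunConfig:
    amplicon: AmpliconSpec
    site: TargetSite
    window: ScoringWindow
    sim: SimulationConfig | None  # exactly one of sim / fastq
    fastq: tuple[str, str] | None
    background: dict
    min_family_size: int = 3
    consensus_threshold: float = 0.7
    max_primer_mismatch: int = 2
    snv_confirmation: str = "mate_overlap"
    seed: int = 0
    raw: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.fastq is None):
            raise ValueError("config must provide exactly one of 'simulate' or 'input'")

    @property
    def config_hash(self) -> str:
        return io.sha256_of_text(json.dumps(self.raw, sort_keys=True, default=str))


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file and/or an override dict.

    With no file and no overrides this is the shipped guide-4-like
    simulation fixture (default amplicon, nick at the guide-4 site,
    65 bp window, control-nick simulation parameters).
    """
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        raw = {**raw, **overrides}

    if "amplicon_fasta" in raw:
        amplicon = io.read_amplicon_fasta(raw["amplicon_fasta"])
    else:
        amplicon = default_amplicon()

    site_cfg = raw.get("site")
    if site_cfg is None:
        site = default_site(amplicon)
    elif "cut" in site_cfg:
        site = TargetSite(
            protospacer=site_cfg.get("protospacer", "N" * 20),
            pam=site_cfg.get("pam", "NGG"),
            strand=site_cfg.get("strand", "top"),
            cut=int(site_cfg["cut"]),
            mode=site_cfg.get("mode", "nick_top"),
        )
    else:
        site = locate_cut_site(
            amplicon,
            site_cfg["protospacer"],
            site_cfg["pam"],
            site_cfg.get("strand", "top"),
            site_cfg.get("mode", "nick_top"),
        )

    window = scoring_window(site, int(raw.get("window_width", 65)), amplicon)

    sim = None
    fastq = None
    if "input" in raw and "simulate" in raw:
        raise ValueError("config must provide exactly one of 'simulate' or 'input'")
    if "input" in raw:
        fastq = (raw["input"]["fastq1"], raw["input"]["fastq2"])
    else:
        sim_kw = dict(raw.get("simulate", {}))
        if "donor_edit" in sim_kw and sim_kw["donor_edit"] is not None:
            sim_kw["donor_edit"] = DonorEdit(**sim_kw["donor_edit"])
        sim = SimulationConfig(**sim_kw)

    background = {k: float(v) for k, v in (raw.get("background") or {}).items()}
    thresholds = raw.get("thresholds", {})
    return RunConfig(
        amplicon=amplicon,
        site=site,
        window=window,
        sim=sim,
        fastq=fastq,
        background=background,
        min_family_size=int(thresholds.get("min_family_size", 3)),
        consensus_threshold=float(thresholds.get("consensus_threshold", 0.7)),
        max_primer_mismatch=int(thresholds.get("max_primer_mismatch", 2)),
        snv_confirmation=raw.get("snv_confirmation", "mate_overlap"),
        seed=int(raw.get("seed", 0)),
        raw=raw,
    )


def _layout(cfg: RunConfig):
    umi_len = cfg.sim.umi_len if cfg.sim else int(cfg.raw.get("umi_len", 10))
    layout = default_layout(cfg.amplicon, umi_len=umi_len,
                            max_primer_mismatch=cfg.max_primer_mismatch)
    return layout


def run_simulate(cfg: RunConfig, outdir: Path | None = None):
    """Simulate molecules and reads; optionally write FASTQ + truth TSV."""
    if cfg.sim is None:
        raise ValueError("config has no simulate block")
    layout = _layout(cfg)
    check_geometry(cfg.sim, cfg.amplicon, cfg.window,
                   len(layout.fwd_primer), len(layout.rev_primer))
    records = simulate_library(cfg.sim, cfg.amplicon, cfg.site, rng_for(cfg.seed, "simulate"))
    pairs = render_reads(records, cfg.sim, rng_for(cfg.seed, "render"))
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_fastq_pair(pairs, outdir / "reads_R1.fastq", outdir / "reads_R2.fastq")
        io.write_truth_table(records, outdir / "truth.tsv")
    return records, pairs


def run_consensus(cfg: RunConfig, outdir: Path | None = None):
    """Read (or simulate) raw pairs and build SSCS consensus molecules."""
    if cfg.fastq is not None:
        raw_pairs = io.read_fastq_pair(*cfg.fastq)
    else:
        _, pairs = run_simulate(cfg, outdir)
        raw_pairs = [(p.seq1, p.seq2) for p in pairs]
    layout = _layout(cfg)
    consensus, stats = consensus_pipeline(
        raw_pairs, layout, cfg.min_family_size, cfg.consensus_threshold
    )
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_consensus_table(consensus, outdir / "consensus.tsv")
        io.write_json(dataclasses.asdict(stats), outdir / "consensus_stats.json")
    return consensus, stats


def run_call(cfg: RunConfig, outdir: Path | None = None, write_vcf: bool = False):
    """Consensus -> per-molecule calls."""
    consensus, cstats = run_consensus(cfg, outdir)
    rules = CallRules(snv_confirmation=cfg.snv_confirmation,
                      donor_edit=cfg.sim.donor_edit if cfg.sim else None)
    calls, stats = call_library(consensus, cfg.amplicon, cfg.window, rules)
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_calls_table(calls, outdir / "calls.tsv")
        if write_vcf:
            (outdir / "events.vcf").write_text(
                "\n".join(io.events_to_vcf_lines(calls, cfg.amplicon)) + "\n"
            )
    return calls, {"consensus": dataclasses.asdict(cstats), "calling": dataclasses.asdict(stats)}


def profile_calls(calls, cfg: RunConfig, outdir: Path | None = None) -> dict:
    """Calls -> summary JSON dict + profile/histogram tables."""
    summary = condition_summary(calls, cfg.background)
    profile = fractional_decrease_map(calls, cfg.window, cfg.amplicon)
    del_hist = deletion_length_histogram(calls)
    ins_hist = insertion_length_histogram(calls)
    n_pass = sum(c.passes for c in calls)
    body = (cfg.sim.read_len - cfg.sim.umi_len) if cfg.sim else None
    cov = (
        coverage(CoverageInputs(2 * n_pass, body, cfg.amplicon.length))
        if body and n_pass
        else None
    )
    out = {
        "summary": summary.as_dict(),
        "asymmetry_index": asymmetry_index(profile, cfg.site.cut),
        "coverage": cov,
        "seed": cfg.seed,
    }
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_profile_tsv(profile, outdir / "position_profile.tsv")
        io.write_histogram_tsv(del_hist, outdir / "deletion_lengths.tsv")
        io.write_histogram_tsv(ins_hist, outdir / "insertion_lengths.tsv")
        io.write_json(out, outdir / "summary.json")
    return out


def run_profile(cfg: RunConfig, outdir: Path | None = None, calls_path: str | None = None) -> dict:
    if calls_path is not None:
        calls = io.read_calls_table(calls_path)
    else:
        calls, _ = run_call(cfg, None)
    return profile_calls(calls, cfg, outdir)


def run_all(cfg: RunConfig, outdir: Path) -> dict:
    """Full run: simulate-or-read -> consensus -> call -> profile -> manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    calls, stage_stats = run_call(cfg, outdir, write_vcf=True)
    result = profile_calls(calls, cfg, outdir)
    manifest = {
        "package": "nickseq",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash,
        "stats": stage_stats,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    io.write_json(manifest, outdir / "manifest.json")
    return result
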