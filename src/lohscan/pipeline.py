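"""End-to-end orchestration: simulate -> call -> report.

These functions are the library entry points the command-line interface
wraps. Each stage is deterministic given its seed; reports carry the
configuration and seed used.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .coverage import compute_rc, smooth_and_bin, DEFAULT_EDGES, DEFAULT_WINDOW, DEFAULT_MIN_DEPTH
from .events import (
    annotate_junctions, breakpoint_position, classify, merge_complex, segment,
    DEFAULT_MERGE_DIST, DEFAULT_MERGE_SNPS, DEFAULT_MIN_SNPS, LARGE_THRESHOLD,
)
from .model import ExperimentDesign, GenomeMap, WHOLE_CHROM, paper_design
from .simulate import (
    DEFAULT_RATES, SimParams, default_genome, plant_alterations,
    synthesize_profiles,
)
from .stats import (
    WT_REFERENCE_RATES, feature_association, hotspot_scan, rate_table,
)
from .spectrum import spectrum_table

log = logging.getLogger(__name__)


@dataclass
class CallerParams:
    window: int = DEFAULT_WINDOW
    edges: tuple = DEFAULT_EDGES
    min_depth: int = DEFAULT_MIN_DEPTH
    min_snps: int = DEFAULT_MIN_SNPS
    merge_dist: int = DEFAULT_MERGE_DIST
    merge_snps: int = DEFAULT_MERGE_SNPS
    large_threshold: int = LARGE_THRESHOLD


@dataclass
class StatsParams:
    alpha: float = 0.05
    hotspot_window: int = 65_000
    hotspot_step: int = 10_000
    n_perm: int = 10_000
    seed: int = 0


@dataclass
class PipelineConfig:
    scale: float = 1.0
    seed: int = 0
    depth: float = 40.0
    rates: dict = field(default_factory=lambda: dict(DEFAULT_RATES))
    caller: CallerParams = field(default_factory=CallerParams)
    stats: StatsParams = field(default_factory=StatsParams)
    reference_rates: dict = field(default_factory=lambda: dict(WT_REFERENCE_RATES))
    schema_version: int = 1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if doc.get("schema_version", 1) != 1:
            raise ValueError("unsupported config schema version")
        cfg = cls()
        for key in ("scale", "seed", "depth", "rates", "reference_rates"):
            if key in doc:
                setattr(cfg, key, doc[key])
        if "caller" in doc:
            cfg.caller = CallerParams(**doc["caller"])
        if "stats" in doc:
            cfg.stats = StatsParams(**doc["stats"])
        return cfg


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def call_isolate(profile, genome: GenomeMap, params: Optional[CallerParams] = None):
    """RC -> smoothing/binning -> segmentation -> classification for one isolate."""
    params = params or CallerParams()
    track = compute_rc(profile, genome)
    track = smooth_and_bin(track, window=params.window, edges=params.edges,
                           min_depth=params.min_depth)
    tracts = segment(track)
    events = classify(tracts, genome, isolate_id=profile.isolate_id,
                      min_snps=params.min_snps,
                      large_threshold=params.large_threshold)
    events = merge_complex(events, genome, merge_dist=params.merge_dist,
                           merge_snps=params.merge_snps)
    return events, track


def call_experiment(profiles: list, genome: GenomeMap,
                    params: Optional[CallerParams] = None):
    """Call all isolates and annotate junctions/translocations genome-wide."""
    if not profiles:
        raise ValueError("no profiles to call")
    params = params or CallerParams()
    all_events = []
    for p in profiles:
        events, _ = call_isolate(p, genome, params)
        counts: dict = {}
        for e in events:
            counts[e.event_class] = counts.get(e.event_class, 0) + 1
        log.info("isolate %s: %s", p.isolate_id,
                 ", ".join(f"{k}={v}" for k, v in sorted(counts.items())) or "no events")
        all_events.extend(events)
    all_events, translocations = annotate_junctions(all_events, genome)
    return all_events, translocations


def loh_breakpoints(events: list) -> pd.DataFrame:
    """Breakpoint midpoints of LOH events, the input to hotspot statistics."""
    rows = []
    for e in events:
        if e.event_class not in ("I_LOH", "T_LOH"):
            continue
        for pos in breakpoint_position(e):
            rows.append({"chrom": e.chromosome, "pos": pos})
    return pd.DataFrame(rows, columns=["chrom", "pos"])


# ---------------------------------------------------------------------------
# stage commands
# ---------------------------------------------------------------------------

def cmd_simulate(outdir: str, config: Optional[PipelineConfig] = None,
                 design: Optional[ExperimentDesign] = None,
                 force: bool = False) -> dict:
    """Write a complete synthetic experiment (genome, profiles, truth)."""
    config = config or PipelineConfig()
    if os.path.isdir(outdir) and os.listdir(outdir) and not force:
        raise FileExistsError(f"output dir {outdir!r} is not empty (use force)")
    os.makedirs(outdir, exist_ok=True)
    design = design or paper_design()
    genome = default_genome(scale=config.scale, seed=config.seed)
    truth = plant_alterations(genome, rates=config.rates, design=design,
                              seed=config.seed + 1)
    profiles = synthesize_profiles(genome, truth, depth=config.depth,
                                   seed=config.seed + 2)
    lio.write_genome_map(genome, outdir)
    lio.write_profiles(profiles, os.path.join(outdir, "profiles.tsv"))
    lio.write_json(truth.to_dict(), os.path.join(outdir, "truth.json"))
    meta = {"seed": config.seed, "scale": config.scale, "depth": config.depth,
            "config_hash": config.digest(),
            "n_isolates": len(design.isolates),
            "total_divisions": design.total_divisions}
    lio.write_json(meta, os.path.join(outdir, "metadata.json"))
    return meta


def cmd_call(dataset_dir: str, outdir: str,
             config: Optional[PipelineConfig] = None) -> dict:
    """Run the caller over a dataset directory written by :func:`cmd_simulate`."""
    config = config or PipelineConfig()
    genome = lio.read_genome_map(os.path.join(dataset_dir, "genome.yaml"))
    profiles = lio.read_profiles(os.path.join(dataset_dir, "profiles.tsv"), genome)
    events, translocations = call_experiment(profiles, genome, config.caller)
    os.makedirs(outdir, exist_ok=True)
    lio.write_events(events, os.path.join(outdir, "events"))
    tr = pd.DataFrame(
        [{"isolate": t.isolate_id, "del_event": t.del_event.event_id,
          "dup_event": t.dup_event.event_id, "repeat_family": t.repeat_family}
         for t in translocations],
        columns=["isolate", "del_event", "dup_event", "repeat_family"])
    tr.to_csv(os.path.join(outdir, "translocations.tsv"), sep="\t", index=False)
    return {"n_events": len(events), "n_translocations": len(translocations)}


def cmd_report(events: list, mutations: list, design: ExperimentDesign,
               genome: GenomeMap, outdir: Optional[str] = None,
               config: Optional[PipelineConfig] = None,
               association_tracks: Optional[list] = None) -> dict:
    """Rate table, hotspot scan, feature associations and mutation spectrum."""
    config = config or PipelineConfig()
    sp = config.stats
    report = {}
    report["rates"] = rate_table(events, mutations, design,
                                 reference_rates=config.reference_rates,
                                 alpha=sp.alpha)
    bp = loh_breakpoints(events)
    if len(bp):
        windows, regions = hotspot_scan(bp, genome, window=sp.hotspot_window,
                                        step=sp.hotspot_step, alpha=sp.alpha)
        report["hotspot_windows"] = pd.DataFrame(
            [dataclasses.asdict(w) for w in windows])
        report["hotspot_regions"] = pd.DataFrame(
            regions, columns=["chrom", "start", "end"])
        tracks = association_tracks or [
            t for t in ("replication_origin", "termination_zone", "snRNA_gene",
                        "transcription_high", "transcription_low")
            if len(genome.track(t))
        ]
        if tracks:
            assoc = feature_association(bp, genome, tracks, n_perm=sp.n_perm,
                                        seed=sp.seed)
            report["associations"] = pd.DataFrame(
                [dataclasses.asdict(a) for a in assoc])
    report["spectrum"] = spectrum_table(mutations, design, genome)
    meta = {"config_hash": config.digest(), "seed": config.seed,
            "total_divisions": design.total_divisions}
    if outdir:
        os.makedirs(outdir, exist_ok=True)
        for name, df in report.items():
            df.to_csv(os.path.join(outdir, f"{name}.tsv"), sep="\t", index=False)
        lio.write_json(meta, os.path.join(outdir, "report_metadata.json"))
    report["metadata"] = meta
    return report
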