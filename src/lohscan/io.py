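"""Readers and writers for the pipeline's file formats.

Internal coordinates are 1-based inclusive; BED files (0-based half-open) are
converted exactly at this boundary: ``(start0, end0) = (pos_start - 1, pos_end)``.
Readers reject malformed input rather than silently coercing.
"""
from __future__ import annotations

import json
import logging
import os
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .model import (
    Chromosome, EventCall, GenomeMap, IsolateProfile, MutationCall, TandemArray,
)

log = logging.getLogger(__name__)

SNP_COLUMNS = ["chrom", "pos", "allele_P1", "allele_P2"]
PROFILE_COLUMNS = ["isolate", "chrom", "pos", "depth_P1", "depth_P2"]


# ---------------------------------------------------------------------------
# genome map
# ---------------------------------------------------------------------------

def read_genome_map(path: str) -> GenomeMap:
    """Read a genome map from a YAML manifest.

    The manifest lists chromosomes (name, length, centromere interval) and
    tandem arrays inline, and points at a SNP TSV (``chrom, pos, allele_P1,
    allele_P2``) and an optional feature BED whose name field is either
    ``track`` or ``track:label``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    base = os.path.dirname(os.path.abspath(path))

    chromosomes = [
        Chromosome(c["name"], int(c["length"]), int(c["cen_start"]), int(c["cen_end"]))
        for c in doc["chromosomes"]
    ]
    snps = pd.read_csv(os.path.join(base, doc["snps"]), sep="\t")
    missing = [c for c in SNP_COLUMNS if c not in snps.columns]
    if missing:
        raise ValueError(f"SNP table missing columns {missing}")
    if (snps["pos"] < 1).any():
        raise ValueError("SNP position < 1 (positions are 1-based)")

    if doc.get("features"):
        features = read_feature_bed(os.path.join(base, doc["features"]))
    else:
        features = None

    arrays = [
        TandemArray(a["name"], a["chromosome"], int(a["start"]), int(a["end"]),
                    int(a["unit_length"]), int(a["ref_units"]))
        for a in doc.get("arrays", [])
    ]
    return GenomeMap(chromosomes, snps, features, arrays)


def write_genome_map(genome: GenomeMap, outdir: str, manifest: str = "genome.yaml") -> str:
    os.makedirs(outdir, exist_ok=True)
    snp_file, feat_file = "snps.tsv", "features.bed"
    genome.snps.to_csv(os.path.join(outdir, snp_file), sep="\t", index=False)
    write_feature_bed(genome.features, os.path.join(outdir, feat_file))
    doc = {
        "chromosomes": [
            {"name": c.name, "length": c.length,
             "cen_start": c.cen_start, "cen_end": c.cen_end}
            for c in genome.chromosomes
        ],
        "snps": snp_file,
        "features": feat_file,
        "arrays": [
            {"name": a.name, "chromosome": a.chromosome, "start": a.start,
             "end": a.end, "unit_length": a.unit_length, "ref_units": a.ref_units}
            for a in genome.arrays
        ],
    }
    path = os.path.join(outdir, manifest)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


def read_feature_bed(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"BED line with <4 fields: {line!r}")
            chrom, start0, end0, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start0 < 0 or end0 <= start0:
                raise ValueError(f"invalid BED interval: {line!r}")
            track, _, label = name.partition(":")
            rows.append({"track": track, "chrom": chrom,
                         "start": start0 + 1, "end": end0, "label": label or track})
    return pd.DataFrame(rows, columns=["track", "chrom", "start", "end", "label"])


def write_feature_bed(features: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        for _, r in features.iterrows():
            name = r["track"] if r["label"] == r["track"] else f"{r['track']}:{r['label']}"
            fh.write(f"{r['chrom']}\t{r['start'] - 1}\t{r['end']}\t{name}\n")


# ---------------------------------------------------------------------------
# isolate profiles
# ---------------------------------------------------------------------------

def read_profiles(path: str, genome: GenomeMap, cycles: Optional[dict] = None) -> list:
    """Read per-isolate allele-depth profiles from TSV or VCF.

    TSV columns: ``isolate, chrom, pos, depth_P1, depth_P2``. VCF input must
    carry per-sample allelic depths (``AD``); the two alleles at each site are
    mapped to parents by matching bases against the genome map. SNPs absent
    from the file are filled with depth (0, 0) and logged; positions not in
    the genome map are rejected.
    """
    if path.endswith((".vcf", ".vcf.gz")):
        table = _vcf_to_table(path, genome)
    else:
        table = pd.read_csv(path, sep="\t")
        missing = [c for c in PROFILE_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"profile table missing columns {missing}")
    if (table[["depth_P1", "depth_P2"]] < 0).to_numpy().any():
        raise ValueError("negative depth in profile table")

    key = genome.snps[["chrom", "pos"]].copy()
    known = set(zip(key["chrom"], key["pos"]))
    bad = [t for t in zip(table["chrom"], table["pos"]) if t not in known]
    if bad:
        raise ValueError(f"profile position not in genome map: {bad[0]}")

    profiles = []
    cycles = cycles or {}
    for iso, grp in table.groupby("isolate", sort=True):
        merged = key.merge(grp[["chrom", "pos", "depth_P1", "depth_P2"]],
                           on=["chrom", "pos"], how="left")
        n_missing = int(merged["depth_P1"].isna().sum())
        if n_missing:
            log.warning("isolate %s: %d SNPs absent from input, filled with depth (0,0)",
                        iso, n_missing)
        merged[["depth_P1", "depth_P2"]] = (
            merged[["depth_P1", "depth_P2"]].fillna(0).astype(int)
        )
        profiles.append(IsolateProfile(str(iso), int(cycles.get(iso, 0)), merged))
    return profiles


def _vcf_to_table(path: str, genome: GenomeMap) -> pd.DataFrame:
    import pysam

    lookup = {
        (r.chrom, r.pos): (r.allele_P1, r.allele_P2)
        for r in genome.snps.itertuples()
    }
    rows = []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            pos = rec.pos  # pysam is 1-based here
            if (rec.chrom, pos) not in lookup:
                raise ValueError(f"VCF record at unknown SNP {rec.chrom}:{pos}")
            a1, a2 = lookup[(rec.chrom, pos)]
            alleles = list(rec.alleles)
            if a1 not in alleles or a2 not in alleles:
                raise ValueError(
                    f"VCF alleles {alleles} at {rec.chrom}:{pos} do not match "
                    f"parental alleles ({a1}, {a2})"
                )
            i1, i2 = alleles.index(a1), alleles.index(a2)
            for sample in samples:
                ad = rec.samples[sample].get("AD")
                if ad is None:
                    raise ValueError(f"VCF sample {sample} lacks AD at {rec.chrom}:{pos}")
                rows.append({"isolate": sample, "chrom": rec.chrom, "pos": pos,
                             "depth_P1": int(ad[i1]), "depth_P2": int(ad[i2])})
    return pd.DataFrame(rows)


def write_profiles(profiles: list, path: str) -> None:
    frames = []
    for p in profiles:
        df = p.depths.copy()
        df.insert(0, "isolate", p.isolate_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# events and mutations
# ---------------------------------------------------------------------------

_EVENT_FIELDS = [
    "event_id", "isolate_id", "event_class", "chromosome", "start", "end", "size",
    "bp_left", "bp_right", "retained_parent", "n_transitions", "is_complex",
    "n_snps", "junction_repeat_family", "large", "state",
]


def _interval_str(iv) -> str:
    return "" if iv is None else f"{iv[0]}-{iv[1]}"


def _parse_interval(s):
    if s in ("", None) or (isinstance(s, float) and np.isnan(s)):
        return None
    lo, _, hi = str(s).partition("-")
    return (int(lo), int(hi))


def events_to_frame(events: list) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append({
            "event_id": e.event_id or "", "isolate_id": e.isolate_id,
            "event_class": e.event_class, "chromosome": e.chromosome,
            "start": e.start, "end": e.end, "size": e.size,
            "bp_left": _interval_str(e.bp_left), "bp_right": _interval_str(e.bp_right),
            "retained_parent": e.retained_parent, "n_transitions": e.n_transitions,
            "is_complex": e.is_complex, "n_snps": e.n_snps,
            "junction_repeat_family": e.junction_repeat_family or "",
            "large": e.large,
            "state": "" if e.state is None else f"{e.state[0]},{e.state[1]}",
        })
    return pd.DataFrame(rows, columns=_EVENT_FIELDS)


def write_events(events: list, path: str) -> tuple:
    """Write events as ``<path>.tsv`` (all fields) and ``<path>.bed`` (tracts).

    The TSV round-trips losslessly through :func:`read_events`.
    """
    tsv, bed = f"{path}.tsv", f"{path}.bed"
    events_to_frame(events).to_csv(tsv, sep="\t", index=False)
    with open(bed, "w") as fh:
        for e in events:
            fh.write(f"{e.chromosome}\t{e.start - 1}\t{e.end}\t{e.event_class}\n")
    return tsv, bed


def read_events(path: str) -> list:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"bp_left": str, "bp_right": str, "state": str,
                            "junction_repeat_family": str, "event_id": str})
    out = []
    for r in df.itertuples():
        out.append(EventCall(
            isolate_id=str(r.isolate_id), event_class=r.event_class,
            chromosome=str(r.chromosome), start=int(r.start), end=int(r.end),
            bp_left=_parse_interval(r.bp_left), bp_right=_parse_interval(r.bp_right),
            retained_parent=r.retained_parent, n_transitions=int(r.n_transitions),
            is_complex=bool(r.is_complex) if not isinstance(r.is_complex, str)
            else r.is_complex == "True",
            n_snps=int(r.n_snps),
            junction_repeat_family=r.junction_repeat_family or None,
            large=bool(r.large) if not isinstance(r.large, str) else r.large == "True",
            event_id=r.event_id or None,
            state=tuple(int(x) for x in r.state.split(",")) if r.state else None,
        ))
    return out


def mutations_to_frame(mutations: list) -> pd.DataFrame:
    cols = ["isolate_id", "chromosome", "position", "kind", "ref", "alt",
            "substitution_class", "context_class", "context_seq"]
    rows = [{c: getattr(m, c) or "" if c in ("substitution_class", "context_class",
                                             "context_seq") else getattr(m, c)
             for c in cols} for m in mutations]
    return pd.DataFrame(rows, columns=cols)


def write_mutations(mutations: list, path: str) -> None:
    mutations_to_frame(mutations).to_csv(path, sep="\t", index=False)


def read_mutations(path: str) -> list:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"substitution_class": str, "context_class": str,
                            "context_seq": str, "ref": str, "alt": str})
    return [
        MutationCall(
            isolate_id=str(r.isolate_id), chromosome=str(r.chromosome),
            position=int(r.position), kind=r.kind, ref=r.ref, alt=r.alt,
            substitution_class=r.substitution_class or None,
            context_class=r.context_class or None,
            context_seq=r.context_seq or None,
        )
        for r in df.itertuples()
    ]


def write_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
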