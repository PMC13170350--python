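"""Synthetic hybrid-diploid mutation-accumulation experiments with known truth.

The generator emulates the statistical structure the analysis assumes: a
diploid heterozygous at ~50,000 SNPs across 16 chromosomes (lengths
proportional to the S. cerevisiae R64 assembly), genome alterations planted
per isolate as Poisson counts of per-division class rates, allele depths
with Poisson counting noise around depth x copies / 2, tandem arrays
(rDNA-like 9-kb units, CUP1-like) and terminal TG1-3 telomere repeat runs.

Event placement is uniform per bp — no intrinsic hotspots — so hotspot
statistics have a clean null; an optional hotspot stanza plants excess
breakpoints in a stated window for power studies.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    Chromosome, ExperimentDesign, GenomeMap, IsolateProfile, MutationCall,
    TandemArray, SUBSTITUTION_CLASSES,
)
from .spectrum import indel_context

log = logging.getLogger(__name__)

# R64 chromosome lengths and centromere midpoints (bp), chrI..chrXVI
_R64_LENGTHS = (
    230218, 813184, 316620, 1531933, 576874, 270161, 1090940, 562643,
    439888, 745751, 666816, 1078177, 924431, 784333, 1091291, 948066,
)
_R64_CEN_MID = (
    151523, 238265, 114443, 449766, 152045, 148568, 496979, 105644,
    355687, 436366, 440187, 150887, 268090, 628816, 326643, 556015,
)
_CHROM_NAMES = (
    "chrI", "chrII", "chrIII", "chrIV", "chrV", "chrVI", "chrVII", "chrVIII",
    "chrIX", "chrX", "chrXI", "chrXII", "chrXIII", "chrXIV", "chrXV", "chrXVI",
)

#: mean SNP spacing giving ~50,000 markers at scale 1
SNP_SPACING = sum(_R64_LENGTHS) / 50_000

#: Default planting intensities (events per cell division): the observed
#: class counts of the 46-isolate experiment divided by its 10,858 divisions.
DEFAULT_RATES = {
    "I_LOH": 158 / 10858, "T_LOH": 193 / 10858,
    "I_DEL": 23 / 10858, "I_DUP": 3 / 10858,
    "T_DEL": 9 / 10858, "T_DUP": 8 / 10858,
    "MONOSOMY": 12 / 10858, "TRISOMY": 13 / 10858,
    "TETRASOMY": 1 / 10858, "UPD": 6 / 10858,
    "SNV": 89 / 10858, "INDEL": 14 / 10858,
}

_BASES = "ACGT"


def _default_snv_probs():
    # A:T>T:A at the observed 22/89 share; the remainder spread evenly
    rest = (1 - 22 / 89) / 5
    return {c: (22 / 89 if c == "A:T>T:A" else rest) for c in SUBSTITUTION_CLASSES}


@dataclass
class SimParams:
    """Tunable knobs of the generator; defaults emulate the study conditions."""
    iloh_mean_tract: float = 10_000.0      # bp, geometric tract length (placeholder default)
    complex_fraction: float = 0.21         # share of LOH events given extra transitions
    min_planted_snps: int = 5              # markers a planted tract must contain
    min_event_gap: int = 26_000            # bp kept clear between planted events
                                           # (beyond the caller's complex-merge distance)
    snv_class_probs: dict = field(default_factory=_default_snv_probs)
    indel_context_probs: dict = field(default_factory=lambda: {
        "mononucleotide_run": 8 / 14, "microsatellite": 4 / 14,
        "direct_repeat_flank": 2 / 14,
    })
    rdna_copies_mean: float = 134.0
    rdna_copies_sd: float = 15.0
    cup1_copies_mean: float = 30.0
    cup1_copies_sd: float = 5.0
    telomere_mean: float = 362.0
    telomere_sd: float = 25.0
    max_retries: int = 200


@dataclass
class PlantedEvent:
    """A planted alteration with its exact true breakpoint base positions."""
    event_id: str
    isolate_id: str
    event_class: str
    chromosome: str
    start: int
    end: int
    retained_parent: str
    segments: list            # (start, end, c_P1, c_P2) covering the event
    is_complex: bool = False
    partner_id: Optional[str] = None


@dataclass
class TruthSet:
    events: list
    mutations: list
    array_copies: dict        # isolate -> {array name: copies per haploid genome}
    telomere_lengths: dict    # isolate -> {"chrom:L|R": bp}
    rates: dict               # per-class planted per-division rates
    seed: int
    params: dict

    def events_for(self, isolate_id: str) -> list:
        return [e for e in self.events if e.isolate_id == isolate_id]

    def to_dict(self) -> dict:
        return {
            "events": [asdict(e) for e in self.events],
            "mutations": [asdict(m) for m in self.mutations],
            "array_copies": self.array_copies,
            "telomere_lengths": self.telomere_lengths,
            "rates": self.rates, "seed": self.seed, "params": self.params,
        }


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def _sorted_unique_positions(rng, n: int, length: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length + 1, size=int(n * 1.1) + 8))
    while len(pos) < n:
        pos = np.unique(np.concatenate([pos, rng.integers(1, length + 1, size=n)]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def default_genome(scale: float = 1.0, seed: int = 0,
                   feature_counts: Optional[dict] = None) -> GenomeMap:
    """Sixteen-chromosome genome map at a chosen scale.

    Chromosome lengths and centromere positions are the R64 values times
    ``scale``; SNP markers are placed uniformly at ~241 bp mean spacing
    (~50,000 at scale 1). Repeat elements ("Ty1"/"Ty2" families) are laid out
    so that both same-chromosome and cross-chromosome same-family pairs
    exist; snRNA/origin/termination/transcription tracks are placed at
    configurable densities; an rDNA-like and a CUP1-like tandem array are
    included.
    """
    if scale <= 0 or scale > 1:
        raise ValueError("scale must be in (0, 1]")
    rng = np.random.default_rng(seed)
    chroms = []
    for name, L, cen in zip(_CHROM_NAMES, _R64_LENGTHS, _R64_CEN_MID):
        length = max(int(round(L * scale)), 2000)
        mid = min(max(int(round(cen * scale)), 61), length - 60)
        chroms.append(Chromosome(name, length, mid - 60, mid + 59))

    snp_frames = []
    for c in chroms:
        n = max(2, int(round(c.length / SNP_SPACING)))
        pos = _sorted_unique_positions(rng, n, c.length)
        a1 = rng.choice(list(_BASES), size=n)
        shift = rng.integers(1, 4, size=n)
        a2 = np.array([_BASES[(_BASES.index(b) + s) % 4] for b, s in zip(a1, shift)])
        snp_frames.append(pd.DataFrame(
            {"chrom": c.name, "pos": pos, "allele_P1": a1, "allele_P2": a2}))
    snps = pd.concat(snp_frames, ignore_index=True)

    feats = []
    elem_len = max(500, int(round(6000 * scale)))

    def _place_repeat(family, chrom: Chromosome, frac):
        start = int(round(chrom.length * frac))
        start = min(max(start, 1), chrom.length - elem_len)
        feats.append({"track": "repeat", "chrom": chrom.name,
                      "start": start, "end": start + elem_len - 1, "label": family})

    # same-chromosome Ty1 pairs (unequal-recombination substrates)
    for ci in (3, 6, 11, 14):  # chrIV, chrVII, chrXII, chrXV
        u = rng.uniform(0.55, 0.68)
        sep = rng.uniform(0.05, 0.09)
        _place_repeat("Ty1", chroms[ci], u)
        _place_repeat("Ty1", chroms[ci], u + sep)
    # dispersed Ty1 singles (translocation substrates)
    for ci in (1, 9, 12, 13):  # chrII, chrX, chrXIII, chrXIV
        _place_repeat("Ty1", chroms[ci], rng.uniform(0.25, 0.45))
    # a second, smaller family
    u = rng.uniform(0.3, 0.4)
    _place_repeat("Ty2", chroms[4], u)
    _place_repeat("Ty2", chroms[4], u + rng.uniform(0.06, 0.1))
    _place_repeat("Ty2", chroms[8], rng.uniform(0.5, 0.7))

    counts = {"snRNA_gene": 20, "replication_origin": 100, "termination_zone": 50,
              "transcription_high": 150, "transcription_low": 150}
    sizes = {"snRNA_gene": 150, "replication_origin": 300, "termination_zone": 1000,
             "transcription_high": 1500, "transcription_low": 1500}
    counts.update(feature_counts or {})
    lengths = np.array([c.length for c in chroms], float)
    probs = lengths / lengths.sum()
    for track, n in counts.items():
        size = min(sizes.get(track, 500), min(c.length for c in chroms) // 4)
        which = rng.choice(len(chroms), size=n, p=probs)
        for ci in which:
            c = chroms[ci]
            start = int(rng.integers(1, max(2, c.length - size)))
            feats.append({"track": track, "chrom": c.name,
                          "start": start, "end": start + size - 1, "label": track})
    features = pd.DataFrame(feats, columns=["track", "chrom", "start", "end", "label"])

    unit_r = max(500, int(round(9000 * scale)))
    unit_c = max(200, int(round(2000 * scale)))
    xii, viii = chroms[11], chroms[7]
    r_start = min(int(round(xii.length * 0.42)), xii.length - 2 * unit_r - 1)
    c_start = min(int(round(viii.length * 0.38)), viii.length - 2 * unit_c - 1)
    arrays = [
        TandemArray("rDNA", "chrXII", r_start, r_start + 2 * unit_r - 1, unit_r, 2),
        TandemArray("CUP1", "chrVIII", c_start, c_start + 2 * unit_c - 1, unit_c, 2),
    ]
    return GenomeMap(chroms, snps, features, arrays)


# ---------------------------------------------------------------------------
# event planting
# ---------------------------------------------------------------------------

class _Placer:
    """Tracks occupied intervals per chromosome for one isolate."""

    def __init__(self, genome: GenomeMap, gap: int):
        self.genome = genome
        self.gap = gap
        self.occupied: dict = {c: [] for c in genome.chrom_names}
        self.whole: set = set()

    def free(self, chrom: str, lo: int, hi: int, gap: Optional[int] = None) -> bool:
        if chrom in self.whole:
            return False
        g = self.gap if gap is None else gap
        return all(hi + g < s or lo - g > e
                   for s, e in self.occupied[chrom])

    def take(self, chrom: str, lo: int, hi: int):
        self.occupied[chrom].append((lo, hi))

    def take_whole(self, chrom: str) -> bool:
        if chrom in self.whole or self.occupied[chrom]:
            return False
        self.whole.add(chrom)
        self.occupied[chrom].append((1, self.genome.chrom_lengths[chrom]))
        return True


def _repeat_pairs(genome: GenomeMap, same_chrom: bool) -> list:
    reps = genome.track("repeat")
    pairs = []
    for fam, grp in reps.groupby("label"):
        elems = list(grp.itertuples())
        for a, b in itertools.combinations(elems, 2):
            if (a.chrom == b.chrom) == same_chrom:
                pairs.append((fam, a, b))
    return pairs


def _mid(elem) -> int:
    return (elem.start + elem.end) // 2


def _snps_in(genome, chrom, lo, hi) -> int:
    pos = genome.snp_positions(chrom)
    return int(np.searchsorted(pos, hi, "right") - np.searchsorted(pos, lo, "left"))


def plant_alterations(genome: GenomeMap, rates: Optional[dict] = None,
                      design: Optional[ExperimentDesign] = None,
                      params: Optional[SimParams] = None,
                      seed: int = 0) -> TruthSet:
    """Draw and place alterations for every isolate of a design.

    Per isolate the count of each class is Poisson(rate x divisions).
    Interstitial LOH tract lengths are geometric (configurable mean);
    terminal LOH breakpoints are uniform over chromosome arms; DEL/DUP
    events join a same-family repeat pair — same-chromosome pairs give
    interstitial events, cross-chromosome pairs are planted as a paired
    T_DEL + T_DUP (a reciprocal translocation's products) at the mean of the
    two terminal rates. Whole-chromosome classes occupy a free chromosome.
    A fraction of LOH events receives extra alternating tracts (complex
    events). Overlapping placements are re-drawn; placement that cannot
    succeed after bounded retries raises.
    """
    from .model import paper_design
    rates = dict(DEFAULT_RATES, **(rates or {}))
    if any(v < 0 for v in rates.values()):
        raise ValueError("rates must be >= 0")
    design = design or paper_design()
    params = params or SimParams()
    rng = np.random.default_rng(seed)

    trans_rate = (rates.get("T_DEL", 0.0) + rates.get("T_DUP", 0.0)) / 2
    planted_rates = dict(rates)
    planted_rates["T_DEL"] = planted_rates["T_DUP"] = trans_rate

    lengths = genome.chrom_lengths
    chrom_names = genome.chrom_names
    probs = np.array([lengths[c] for c in chrom_names], float)
    probs /= probs.sum()
    same_pairs = _repeat_pairs(genome, same_chrom=True)
    cross_pairs = _repeat_pairs(genome, same_chrom=False)

    events, mutations = [], []
    array_truth, telo_truth = {}, {}
    counter = itertools.count(1)

    for iso_id, cycles in design.isolates:
        div = cycles * design.divisions_per_cycle
        placer = _Placer(genome, params.min_event_gap)

        def n_of(cls, rate=None):
            r = rates.get(cls, 0.0) if rate is None else rate
            return rng.poisson(r * div)

        # whole-chromosome classes first: they need an untouched chromosome
        for cls in ("MONOSOMY", "TRISOMY", "TETRASOMY", "UPD"):
            for _ in range(n_of(cls)):
                for _try in range(params.max_retries):
                    chrom = rng.choice(chrom_names)
                    if placer.take_whole(chrom):
                        events.append(_whole_chrom_event(
                            next(counter), iso_id, cls, chrom, lengths[chrom], rng))
                        break
                else:
                    raise RuntimeError("could not place whole-chromosome event")

        for _ in range(rng.poisson(trans_rate * div)):
            ev = _place_translocation(genome, cross_pairs, placer, params, rng,
                                      iso_id, counter)
            events.extend(ev)

        for cls in ("I_DEL", "I_DUP"):
            for _ in range(n_of(cls)):
                events.append(_place_interstitial_rearrangement(
                    genome, same_pairs, placer, params, rng, iso_id, cls, counter))

        for _ in range(n_of("T_LOH")):
            events.append(_place_terminal_loh(genome, placer, params, rng,
                                              iso_id, counter))
        for _ in range(n_of("I_LOH")):
            events.append(_place_interstitial_loh(genome, probs, placer, params,
                                                  rng, iso_id, counter))

        mutations.extend(_plant_snvs(genome, probs, rng, iso_id, n_of("SNV"), params))
        mutations.extend(_plant_indels(genome, probs, rng, iso_id, n_of("INDEL"), params))

        array_truth[iso_id] = {
            "rDNA": float(max(1.0, rng.normal(params.rdna_copies_mean,
                                              params.rdna_copies_sd))),
            "CUP1": float(max(1.0, rng.normal(params.cup1_copies_mean,
                                              params.cup1_copies_sd))),
        }
        telo_truth[iso_id] = {
            f"{c}:{side}": int(max(0.0, round(rng.normal(params.telomere_mean,
                                                         params.telomere_sd))))
            for c in chrom_names for side in ("L", "R")
        }

    events = [e for e in events if e is not None]
    return TruthSet(
        events=events, mutations=mutations, array_copies=array_truth,
        telomere_lengths=telo_truth, rates=planted_rates, seed=int(seed),
        params={"design": {"isolates": list(design.isolates),
                           "divisions_per_cycle": design.divisions_per_cycle,
                           "total_divisions": design.total_divisions},
                **{k: (v if np.isscalar(v) else dict(v) if isinstance(v, dict) else v)
                   for k, v in asdict(params).items()}},
    )


def _whole_chrom_event(eid, iso_id, cls, chrom, length, rng) -> PlantedEvent:
    parent = rng.choice(["P1", "P2"])
    state = {
        "MONOSOMY": {"P1": (1, 0), "P2": (0, 1)},
        "TRISOMY": {"P1": (2, 1), "P2": (1, 2)},
        "TETRASOMY": {"P1": (2, 2), "P2": (2, 2)},
        "UPD": {"P1": (2, 0), "P2": (0, 2)},
    }[cls][parent]
    return PlantedEvent(f"truth:{eid}", iso_id, cls, chrom, 1, length,
                        "none" if cls == "TETRASOMY" else parent,
                        [(1, length, state[0], state[1])])


def _loh_state(parent: str) -> tuple:
    return (2, 0) if parent == "P1" else (0, 2)


def _place_interstitial_loh(genome, probs, placer, params, rng, iso_id, counter):
    names = genome.chrom_names
    for _try in range(params.max_retries):
        chrom = names[rng.choice(len(names), p=probs)]
        L = genome.chrom_lengths[chrom]
        span = int(rng.geometric(1.0 / max(params.iloh_mean_tract, 2.0)))
        start = int(rng.integers(1, max(2, L - span)))
        end = start + span - 1
        pos = genome.snp_positions(chrom)
        if len(pos) < params.min_planted_snps + 2:
            continue
        # keep strictly interior: flanking baseline SNPs must exist
        if start <= pos[0] or end >= pos[-1]:
            continue
        if _snps_in(genome, chrom, start, end) < params.min_planted_snps:
            continue
        gap = None if _try < params.max_retries // 2 else placer.gap // 8
        if not placer.free(chrom, start, end, gap):
            continue
        placer.take(chrom, start, end)
        parent = str(rng.choice(["P1", "P2"]))
        c1, c2 = _loh_state(parent)
        ev = PlantedEvent(f"truth:{next(counter)}", iso_id, "I_LOH", chrom,
                          start, end, parent, [(start, end, c1, c2)])
        return _maybe_complex(ev, genome, params, rng)
    raise RuntimeError("could not place interstitial LOH after bounded retries")


def _place_terminal_loh(genome, placer, params, rng, iso_id, counter):
    names = genome.chrom_names
    # arm chosen with probability proportional to arm length, breakpoint uniform
    arms = []
    for c in genome.chromosomes:
        arms.append((c.name, "L", 1, c.cen_start - 1))
        arms.append((c.name, "R", c.cen_end + 1, c.length))
    weights = np.array([max(hi - lo, 1) for _, _, lo, hi in arms], float)
    weights /= weights.sum()
    for _try in range(params.max_retries):
        chrom, side, lo, hi = arms[rng.choice(len(arms), p=weights)]
        bp = int(rng.integers(lo, hi + 1))
        L = genome.chrom_lengths[chrom]
        start, end = (1, bp) if side == "L" else (bp, L)
        pos = genome.snp_positions(chrom)
        if len(pos) < params.min_planted_snps + 2:
            continue
        # a baseline SNP must remain on the centromere-proximal side
        if (side == "L" and end >= pos[-1]) or (side == "R" and start <= pos[0]):
            continue
        if _snps_in(genome, chrom, start, end) < params.min_planted_snps:
            continue
        gap = None if _try < params.max_retries // 2 else placer.gap // 8
        if not placer.free(chrom, start, end, gap):
            continue
        placer.take(chrom, start, end)
        parent = str(rng.choice(["P1", "P2"]))
        c1, c2 = _loh_state(parent)
        ev = PlantedEvent(f"truth:{next(counter)}", iso_id, "T_LOH", chrom,
                          start, end, parent, [(start, end, c1, c2)])
        return _maybe_complex(ev, genome, params, rng, terminal_side=side)
    raise RuntimeError("could not place terminal LOH after bounded retries")


def _maybe_complex(ev, genome, params, rng, terminal_side=None):
    """With the configured probability, punch short baseline gaps into an LOH
    tract so the called event shows extra transitions (a complex event)."""
    if rng.random() >= params.complex_fraction:
        return ev
    pos = genome.snp_positions(ev.chromosome)
    inside = pos[(pos >= ev.start) & (pos <= ev.end)]
    n = len(inside)
    min_seg = max(params.min_planted_snps, 3)
    n_gaps = 2 if (n >= 4 * min_seg + 14 and rng.random() < 0.5) else 1
    gaps = [int(rng.integers(3, 7)) for _ in range(n_gaps)]
    need = (n_gaps + 1) * min_seg + sum(gaps)
    if n < need + 2:
        return ev  # too few markers to carry extra transitions
    # split the surplus markers randomly over the retained segments
    extra = n - need
    cuts = np.sort(rng.integers(0, extra + 1, size=n_gaps))
    parts = np.diff(np.concatenate([[0], cuts, [extra]]))
    seg_lens = [min_seg + int(p) for p in parts]
    c1, c2 = ev.segments[0][2], ev.segments[0][3]
    segments = []
    i = 0
    for k, sl in enumerate(seg_lens):
        seg_start = ev.start if k == 0 else int(inside[i])
        if k == n_gaps:
            seg_end = ev.end
        else:
            seg_end = int(inside[i + sl - 1])
        segments.append((seg_start, seg_end, c1, c2))
        i += sl + (gaps[k] if k < n_gaps else 0)
    ev.segments = segments
    ev.is_complex = True
    return ev


def _place_interstitial_rearrangement(genome, same_pairs, placer, params, rng,
                                      iso_id, cls, counter):
    if not same_pairs:
        raise ValueError("genome has no same-chromosome same-family repeat pair")
    order = rng.permutation(len(same_pairs))
    for _try in range(params.max_retries):
        fam, a, b = same_pairs[order[_try % len(order)]]
        lo, hi = sorted((_mid(a), _mid(b)))
        chrom = a.chrom
        pos = genome.snp_positions(chrom)
        if lo <= pos[0] or hi >= pos[-1]:
            continue
        if _snps_in(genome, chrom, lo, hi) < params.min_planted_snps:
            continue
        gap = None if _try < params.max_retries // 2 else placer.gap // 8
        if not placer.free(chrom, lo, hi, gap):
            continue
        placer.take(chrom, lo, hi)
        parent = str(rng.choice(["P1", "P2"]))
        if cls == "I_DEL":
            state = (1, 0) if parent == "P1" else (0, 1)
        else:
            state = (2, 1) if parent == "P1" else (1, 2)
        return PlantedEvent(f"truth:{next(counter)}", iso_id, cls, chrom, lo, hi,
                            parent, [(lo, hi, state[0], state[1])])
    log.warning("isolate %s: no usable repeat pair for %s, event skipped", iso_id, cls)
    return None


def _place_translocation(genome, cross_pairs, placer, params, rng, iso_id, counter):
    """Plant the reciprocal products of an ectopic crossover between repeats
    on non-homologous chromosomes: a T_DEL on one and a partner T_DUP on the
    other, both with junctions at the same-family elements."""
    if not cross_pairs:
        raise ValueError("genome has no cross-chromosome same-family repeat pair")
    order = rng.permutation(len(cross_pairs))
    for _try in range(params.max_retries):
        fam, a, b = cross_pairs[order[_try % len(order)]]
        if rng.random() < 0.5:
            a, b = b, a
        placements = []
        ok = True
        for elem, cls in ((a, "T_DEL"), (b, "T_DUP")):
            chrom = elem.chrom
            c = genome.chromosome(chrom)
            mid = _mid(elem)
            # the altered segment runs centromere-distal from the element
            if mid > c.cen_end:
                lo, hi = mid, c.length
            else:
                lo, hi = 1, mid
            pos = genome.snp_positions(chrom)
            if (hi >= pos[-1] and lo <= pos[0]):
                ok = False; break
            if _snps_in(genome, chrom, lo, hi) < params.min_planted_snps:
                ok = False; break
            if not placer.free(chrom, lo, hi):
                ok = False; break
            placements.append((chrom, lo, hi, cls))
        if not ok or placements[0][0] == placements[1][0]:
            continue
        parent = str(rng.choice(["P1", "P2"]))
        out = []
        ids = [next(counter), next(counter)]
        for (chrom, lo, hi, cls), eid, pid in zip(placements, ids, ids[::-1]):
            placer.take(chrom, lo, hi)
            if cls == "T_DEL":
                state = (1, 0) if parent == "P1" else (0, 1)
            else:
                state = (2, 1) if parent == "P1" else (1, 2)
            out.append(PlantedEvent(f"truth:{eid}", iso_id, cls, chrom, lo, hi,
                                    parent, [(lo, hi, state[0], state[1])],
                                    partner_id=f"truth:{pid}"))
        return out
    log.warning("isolate %s: could not place translocation, skipped", iso_id)
    return []


def _plant_snvs(genome, probs, rng, iso_id, n, params):
    classes = list(params.snv_class_probs)
    weights = np.array([params.snv_class_probs[c] for c in classes], float)
    weights /= weights.sum()
    names = genome.chrom_names
    out = []
    for _ in range(n):
        chrom = names[rng.choice(len(names), p=probs)]
        pos = int(rng.integers(1, genome.chrom_lengths[chrom] + 1))
        cls = classes[rng.choice(len(classes), p=weights)]
        ref_pair, alt_pair = cls.split(">")
        i = int(rng.integers(0, 2))  # either strand representation
        ref, alt = ref_pair.split(":")[i], alt_pair.split(":")[i]
        out.append(MutationCall(iso_id, chrom, pos, "SNV", ref, alt,
                                substitution_class=cls))
    return out


def _random_seq(rng, n, alphabet=_BASES):
    return "".join(rng.choice(list(alphabet), size=n))


def _make_indel(rng, context: str) -> tuple:
    """Construct (window, ref, alt, offset) whose context classifies as requested."""
    if context == "mononucleotide_run":
        base = str(rng.choice(list(_BASES)))
        run = int(rng.integers(5, 9))
        others = [b for b in _BASES if b != base]
        left = _random_seq(rng, 8, others)
        right = _random_seq(rng, 20 - run - 8 + 4, others)
        window = (left + base * run + right)[:24]
        offset = 8 + int(rng.integers(0, run))
        anchor = window[offset - 1]
        if rng.random() < 0.5:
            ref, alt = anchor + base, anchor        # 1-bp deletion in the run
        else:
            ref, alt = anchor, anchor + base        # 1-bp insertion
        return window, ref, alt, offset
    if context == "microsatellite":
        b1, b2 = rng.choice(list(_BASES), size=2, replace=False)
        unit = str(b1) + str(b2)
        units = int(rng.integers(4, 6))
        others = [b for b in _BASES if b not in unit]
        left = _random_seq(rng, 6, others)
        right = _random_seq(rng, 8, others)
        window = left + unit * units + right
        offset = 6 + 2 * int(rng.integers(1, units - 1))
        anchor = window[offset - 1]
        ref, alt = anchor + unit, anchor            # one-unit deletion
        return window, ref, alt, offset
    # direct repeat flank: delete one copy of a >=3 bp repeat present nearby
    d = _random_seq(rng, int(rng.integers(3, 5)))
    if len(set(d)) == 1:
        d = d[:-1] + ("A" if d[0] != "A" else "C")
    spacer = _random_seq(rng, int(rng.integers(3, 6)))
    left = _random_seq(rng, 6)
    right = _random_seq(rng, 6)
    window = left + d + spacer + d + right
    offset = len(left) + len(d) + len(spacer)
    anchor = window[offset - 1]
    ref, alt = anchor + d, anchor
    return window, ref, alt, offset


def _plant_indels(genome, probs, rng, iso_id, n, params):
    contexts = list(params.indel_context_probs)
    weights = np.array([params.indel_context_probs[c] for c in contexts], float)
    weights /= weights.sum()
    names = genome.chrom_names
    out = []
    for _ in range(n):
        ctx = contexts[rng.choice(len(contexts), p=weights)]
        for _try in range(params.max_retries):
            window, ref, alt, offset = _make_indel(rng, ctx)
            if indel_context(window, ref, alt, indel_offset=offset) == ctx:
                break
        else:
            raise RuntimeError(f"could not construct a {ctx} indel context")
        chrom = names[rng.choice(len(names), p=probs)]
        pos = int(rng.integers(1, genome.chrom_lengths[chrom] + 1))
        out.append(MutationCall(iso_id, chrom, pos, "INDEL", ref, alt,
                                context_class=ctx, context_seq=window))
    return out


# ---------------------------------------------------------------------------
# profile synthesis
# ---------------------------------------------------------------------------

def synthesize_profiles(genome: GenomeMap, truth: TruthSet, depth: float = 40.0,
                        seed: int = 0, noiseless: bool = False) -> list:
    """Allele depths per SNP for every isolate of a truth set.

    Per-SNP copies (c_P1, c_P2) start at (1, 1) and are overwritten by the
    planted events' segments; each allele depth is Poisson(depth x c / 2),
    or its expectation rounded when ``noiseless`` (for exactness checks).
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    snps = genome.snps
    chrom_index = {c: np.flatnonzero((snps["chrom"] == c).to_numpy())
                   for c in genome.chrom_names}
    pos_by_chrom = {c: snps["pos"].to_numpy()[idx] for c, idx in chrom_index.items()}

    iso_cycles = dict(truth.params["design"]["isolates"])
    profiles = []
    for iso_id, cycles in truth.params["design"]["isolates"]:
        c1 = np.ones(len(snps), int)
        c2 = np.ones(len(snps), int)
        for ev in truth.events_for(iso_id):
            idx = chrom_index[ev.chromosome]
            pos = pos_by_chrom[ev.chromosome]
            for (lo, hi, s1, s2) in ev.segments:
                m = (pos >= lo) & (pos <= hi)
                c1[idx[m]] = s1
                c2[idx[m]] = s2
        lam1 = depth * c1 / 2.0
        lam2 = depth * c2 / 2.0
        if noiseless:
            d1, d2 = np.rint(lam1).astype(int), np.rint(lam2).astype(int)
        else:
            d1, d2 = rng.poisson(lam1), rng.poisson(lam2)
        df = snps[["chrom", "pos"]].copy()
        df["depth_P1"] = d1
        df["depth_P2"] = d2
        profiles.append(IsolateProfile(iso_id, int(iso_cycles[iso_id]), df))
    return profiles


def synthesize_array_depths(genome: GenomeMap, truth: TruthSet, depth: float = 40.0,
                            seed: int = 0, n_positions: int = 1000) -> dict:
    """Mean read depth over each tandem array's collapsed reference unit.

    A cell with C array copies per haploid genome spreads reads from 2C
    cellular units over the ref_units collapsed reference units, so the
    expected unit depth is depth x C / ref_units; positions are Poisson.
    Returns {isolate: {array name: (mean_unit_depth, mean_genome_depth)}}.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for iso_id, copies in truth.array_copies.items():
        out[iso_id] = {}
        for arr in genome.arrays:
            lam = depth * copies[arr.name] / arr.ref_units
            sim = rng.poisson(lam, size=n_positions)
            genome_depth = rng.poisson(depth, size=n_positions)
            out[iso_id][arr.name] = (float(sim.mean()), float(genome_depth.mean()))
    return out


# ---------------------------------------------------------------------------
# telomere reads
# ---------------------------------------------------------------------------

def _tg_run(rng, target: int) -> str:
    if target <= 0:
        return ""
    parts = []
    total = 0
    while total < target:
        unit = "T" + "G" * int(rng.integers(1, 4))
        parts.append(unit)
        total += len(unit)
    run = "".join(parts)
    return run[len(run) - target:]   # trim from the left: truncated leading unit


def synthesize_terminal_reads(genome: GenomeMap, mean_len: float = 362.0,
                              sd: float = 25.0, seed: int = 0,
                              subtelomere: int = 300,
                              lengths: Optional[dict] = None) -> list:
    """One terminal read per chromosome end, ending in a TG1-3 repeat run.

    The run length is Normal(mean_len, sd) truncated at 0 (or taken from
    ``lengths`` keyed ``"chrom:L|R"``); it follows random subtelomeric
    sequence whose final base is never T or G, so the run is exactly
    recoverable. Returns records ``{chrom, side, true_length, seq}``.
    """
    if mean_len <= 0:
        raise ValueError("mean_len must be > 0")
    rng = np.random.default_rng(seed)
    reads = []
    for c in genome.chromosomes:
        for side in ("L", "R"):
            if lengths is not None:
                target = int(lengths[f"{c.name}:{side}"])
            else:
                target = int(max(0.0, round(rng.normal(mean_len, sd))))
            sub = _random_seq(rng, subtelomere - 1) + str(rng.choice(["A", "C"]))
            reads.append({"chrom": c.name, "side": side,
                          "true_length": target, "seq": sub + _tg_run(rng, target)})
    return reads
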