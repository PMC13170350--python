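"""Segmentation of copy tracks into tracts and classification of alterations.

The event taxonomy follows the copy-state geometry of a hybrid diploid that
is heterozygous at every marker. Relative to the baseline per-allele state
(1, 1):

======== =========================== =================================
state     tract interpretation        class
======== =========================== =================================
(2, 0)    copy-neutral homozygosity   I_LOH / T_LOH (or UPD if whole)
(1, 0)    one allele lost             I_DEL / T_DEL (MONOSOMY if whole)
(2, 1)    one allele duplicated       I_DUP / T_DUP (TRISOMY if whole)
(2, 2)    both duplicated             TETRASOMY (whole chromosome)
======== =========================== =================================

``I_`` events are flanked by baseline markers on both sides; ``T_`` events
reach the first or last SNP of the chromosome. Unrecognised states are
surfaced as class OTHER, never dropped.
"""
from __future__ import annotations

import itertools
import logging
from typing import Optional

import numpy as np

from .coverage import CopyTrack
from .model import (
    EventCall, GenomeMap, TranslocationCandidate, Tract,
    INTERSTITIAL, TERMINAL, WHOLE_CHROM,
)

log = logging.getLogger(__name__)

DEFAULT_MIN_SNPS = 5
LARGE_THRESHOLD = 5000      # bp; "large" deletions/duplications exceed this
DEFAULT_MERGE_DIST = 25000  # bp of baseline separating tracts merged as one complex event
DEFAULT_MERGE_SNPS = 100    # baseline SNPs ditto (~25 kb at ~241 bp marker spacing)

_BASELINE = (1, 1)

# interior (non-whole-chromosome) state -> (kind, retained parent)
_STATE_MAP = {
    (2, 0): ("LOH", "P1"), (0, 2): ("LOH", "P2"),
    (1, 0): ("DEL", "P1"), (0, 1): ("DEL", "P2"),
    (2, 1): ("DUP", "P1"), (1, 2): ("DUP", "P2"),
}
_WHOLE_MAP = {
    (1, 0): ("MONOSOMY", "P1"), (0, 1): ("MONOSOMY", "P2"),
    (2, 1): ("TRISOMY", "P1"), (1, 2): ("TRISOMY", "P2"),
    (2, 2): ("TETRASOMY", "none"),
    (2, 0): ("UPD", "P1"), (0, 2): ("UPD", "P2"),
}


def segment(track: CopyTrack) -> list:
    """Partition unmasked SNPs into maximal runs of constant copy state.

    Masked SNPs are excluded and do not break a run when the flanking
    unmasked states agree.
    """
    if not track.binned:
        raise ValueError("track must be binned before segmentation (smooth_and_bin)")
    data = track.data
    tracts = []
    for chrom, idx in data.groupby("chrom", sort=False).indices.items():
        sub = data.iloc[idx]
        keep = ~sub["masked"].to_numpy()
        if not keep.any():
            continue
        pos = sub["pos"].to_numpy()[keep]
        c1 = sub["c_P1"].to_numpy()[keep]
        c2 = sub["c_P2"].to_numpy()[keep]
        change = np.flatnonzero((np.diff(c1) != 0) | (np.diff(c2) != 0))
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change, [len(pos) - 1]])
        for s, e in zip(starts, ends):
            tracts.append(Tract(
                chromosome=str(chrom), i_first=int(s), i_last=int(e),
                pos_first=int(pos[s]), pos_last=int(pos[e]),
                c_P1=int(c1[s]), c_P2=int(c2[s]), n_snps=int(e - s + 1),
            ))
    return tracts


def _clean_tracts(tracts: list, min_snps: int) -> list:
    """Drop sub-threshold non-baseline tracts and coalesce equal-state runs."""
    kept = [t for t in tracts if t.state == _BASELINE or t.n_snps >= min_snps]
    out: list = []
    for t in kept:
        if out and out[-1].state == t.state:
            prev = out[-1]
            out[-1] = Tract(prev.chromosome, prev.i_first, t.i_last,
                            prev.pos_first, t.pos_last, prev.c_P1, prev.c_P2,
                            prev.n_snps + t.n_snps)
        else:
            out.append(t)
    return out


def classify(tracts: list, genome: GenomeMap, isolate_id: str = "",
             min_snps: int = DEFAULT_MIN_SNPS,
             large_threshold: int = LARGE_THRESHOLD,
             track: Optional[CopyTrack] = None) -> list:
    """Turn non-baseline tracts into classified event calls.

    Non-baseline tracts supported by fewer than ``min_snps`` markers are
    treated as counting noise and removed; equal-state neighbours separated
    only by such noise are coalesced, so a real tract fragmented by a short
    depth excursion keeps its identity (in particular its terminal or
    whole-chromosome character). A tract spanning a chromosome's first
    through last retained SNP becomes a whole-chromosome call
    (MONOSOMY/TRISOMY/TETRASOMY/UPD). Breakpoint uncertainty intervals run
    from the nearest flanking retained SNP to the first SNP of the tract;
    terminal events carry a single interval.
    """
    events = []
    counter = itertools.count(1)
    by_chrom: dict = {}
    for t in tracts:
        by_chrom.setdefault(t.chromosome, []).append(t)

    for chrom, chrom_tracts in by_chrom.items():
        chrom_tracts.sort(key=lambda t: t.pos_first)
        chrom_tracts = _clean_tracts(chrom_tracts, min_snps)
        if not chrom_tracts:
            continue
        first_pos = chrom_tracts[0].pos_first
        last_pos = chrom_tracts[-1].pos_last
        for j, t in enumerate(chrom_tracts):
            state = t.state
            if state == _BASELINE or t.n_snps < min_snps:
                continue
            left_term = t.pos_first == first_pos
            right_term = t.pos_last == last_pos
            bp_left = bp_right = None
            if not left_term:
                prev = chrom_tracts[j - 1]
                bp_left = (prev.pos_last, t.pos_first)
            if not right_term:
                nxt = chrom_tracts[j + 1]
                bp_right = (t.pos_last, nxt.pos_first)

            if left_term and right_term:
                kind, parent = _WHOLE_MAP.get(state, ("OTHER", "none"))
                cls, n_trans = kind, 0
            elif state in _STATE_MAP:
                kind, parent = _STATE_MAP[state]
                terminal = left_term or right_term
                cls = ("T_" if terminal else "I_") + kind
                n_trans = 1 if terminal else 2
            else:
                cls, parent, n_trans = "OTHER", "none", 1 if (left_term or right_term) else 2
                log.warning("isolate %s: unmapped copy state %s on %s at %d..%d "
                            "surfaced as OTHER", isolate_id, state, chrom,
                            t.pos_first, t.pos_last)

            size = t.pos_last - t.pos_first + 1
            events.append(EventCall(
                isolate_id=isolate_id, event_class=cls, chromosome=chrom,
                start=t.pos_first, end=t.pos_last,
                bp_left=bp_left, bp_right=bp_right,
                retained_parent=parent, n_transitions=n_trans,
                is_complex=False, n_snps=t.n_snps,
                large=("DEL" in cls or "DUP" in cls) and size > large_threshold,
                event_id=f"{isolate_id}:{chrom}:{next(counter)}",
                state=state,
            ))
    events.sort(key=lambda e: (e.chromosome, e.start))
    return events


def merge_complex(events: list, genome: GenomeMap,
                  merge_dist: int = DEFAULT_MERGE_DIST,
                  merge_snps: int = DEFAULT_MERGE_SNPS) -> list:
    """Merge nearby alteration tracts into single complex events.

    Consecutive non-baseline tracts on one chromosome (same isolate) whose
    separating baseline run is shorter than ``merge_dist`` bp AND carries
    fewer than ``merge_snps`` SNPs are one event with multiple transitions
    (both defaults correspond to ~25 kb at the ~241 bp marker spacing).
    The merged call takes the class of its largest constituent tract and is
    flagged complex when its transition count exceeds the simple-event count
    (2 interstitial, 1 terminal).
    """
    out = []
    keyfn = lambda e: (e.isolate_id, e.chromosome)
    for _, group in itertools.groupby(sorted(events, key=lambda e: (keyfn(e), e.start)),
                                      key=keyfn):
        group = list(group)
        cluster = [group[0]]
        for e in group[1:]:
            prev = cluster[-1]
            if e.event_class in WHOLE_CHROM or prev.event_class in WHOLE_CHROM:
                mergeable = False
            else:
                gap_bp = e.start - prev.end
                snp_pos = genome.snp_positions(e.chromosome)
                gap_snps = int(np.searchsorted(snp_pos, e.start, "left")
                               - np.searchsorted(snp_pos, prev.end, "right"))
                mergeable = gap_bp < merge_dist and gap_snps < merge_snps
            if mergeable:
                cluster.append(e)
            else:
                out.append(_merge_cluster(cluster, genome))
                cluster = [e]
        out.append(_merge_cluster(cluster, genome))
    out.sort(key=lambda e: (e.isolate_id, e.chromosome, e.start))
    return out


# class of the merged event when its span reaches one chromosome end / both ends
_TERMINALIZE = {"I_LOH": "T_LOH", "I_DEL": "T_DEL", "I_DUP": "T_DUP"}
_WHOLEIZE = {"I_LOH": "UPD", "T_LOH": "UPD", "I_DEL": "MONOSOMY",
             "T_DEL": "MONOSOMY", "I_DUP": "TRISOMY", "T_DUP": "TRISOMY"}


def _merge_cluster(cluster: list, genome: GenomeMap) -> EventCall:
    if len(cluster) == 1:
        return cluster[0]
    largest = max(cluster, key=lambda e: e.size)
    first, last = cluster[0], cluster[-1]
    n_trans = sum(e.n_transitions for e in cluster)
    cls = largest.event_class
    # a merged span reaching a chromosome end is terminal; reaching both ends
    # is a whole-chromosome alteration, whatever noise tract split it
    snp_pos = genome.snp_positions(largest.chromosome)
    at_left = first.start <= snp_pos[0] or first.bp_left is None
    at_right = last.end >= snp_pos[-1] or last.bp_right is None
    if at_left and at_right:
        if cls in _WHOLEIZE:
            cls = _WHOLEIZE[cls]
        elif cls == "OTHER" and largest.state in _WHOLE_MAP:
            cls = _WHOLE_MAP[largest.state][0]
    elif at_left or at_right:
        cls = _TERMINALIZE.get(cls, cls)
    simple = 1 if cls in TERMINAL else (0 if cls in WHOLE_CHROM else 2)
    merged = EventCall(
        isolate_id=largest.isolate_id, event_class=cls,
        chromosome=largest.chromosome, start=first.start, end=last.end,
        bp_left=first.bp_left, bp_right=last.bp_right,
        retained_parent=largest.retained_parent, n_transitions=n_trans,
        is_complex=n_trans > simple, n_snps=sum(e.n_snps for e in cluster),
        large=("DEL" in cls or "DUP" in cls) and (last.end - first.start + 1) > LARGE_THRESHOLD,
        event_id=largest.event_id,
        state=largest.state,
    )
    return merged


def _overlapping_families(genome: GenomeMap, chrom: str, interval,
                          repeat_track: str) -> set:
    feats = genome.features
    m = (feats["track"] == repeat_track) & (feats["chrom"] == chrom)
    if interval is not None:
        lo, hi = interval
        m &= (feats["end"] >= lo) & (feats["start"] <= hi)
    return set(feats.loc[m, "label"])


def annotate_junctions(events: list, genome: GenomeMap,
                       repeat_track: str = "repeat") -> tuple:
    """Attach junction repeat families and pair terminal events into translocations.

    An interstitial DEL/DUP gets a family when both breakpoint uncertainty
    intervals overlap repeat elements of that family (non-allelic ectopic
    recombination between a same-family pair). A terminal DEL/DUP gets one
    when its single interval overlaps a family that has another element
    elsewhere in the genome. Within each isolate, a T_DEL and a T_DUP on
    different chromosomes sharing a family are emitted as one
    :class:`TranslocationCandidate`.

    Returns ``(events, translocation_candidates)``; events are annotated in
    place, absence of repeat overlap leaves the field empty.
    """
    feats = genome.features
    all_by_family: dict = {}
    for _, r in feats[feats["track"] == repeat_track].iterrows():
        all_by_family.setdefault(r["label"], []).append((r["chrom"], r["start"], r["end"]))

    for e in events:
        if not any(k in e.event_class for k in ("DEL", "DUP")):
            continue
        intervals = [iv for iv in (e.bp_left, e.bp_right) if iv is not None]
        if not intervals:
            continue
        fams = None
        for iv in intervals:
            f = _overlapping_families(genome, e.chromosome, iv, repeat_track)
            fams = f if fams is None else (fams & f)
        if e.event_class in TERMINAL and fams:
            # require a same-family element somewhere outside the junction
            iv = intervals[0]
            fams = {
                fam for fam in fams
                if any(not (c == e.chromosome and s <= iv[1] and t >= iv[0])
                       for (c, s, t) in all_by_family.get(fam, []))
            }
        if fams:
            e.junction_repeat_family = sorted(fams)[0]

    candidates = []
    by_iso: dict = {}
    for e in events:
        by_iso.setdefault(e.isolate_id, []).append(e)
    for iso, evs in by_iso.items():
        dels = [e for e in evs if e.event_class == "T_DEL" and e.junction_repeat_family]
        dups = [e for e in evs if e.event_class == "T_DUP" and e.junction_repeat_family]
        used = set()
        for d in dels:
            for u in dups:
                if (id(u) not in used and u.chromosome != d.chromosome
                        and u.junction_repeat_family == d.junction_repeat_family):
                    candidates.append(TranslocationCandidate(
                        iso, d, u, d.junction_repeat_family))
                    used.add(id(u))
                    break
    return events, candidates


def breakpoint_position(event: EventCall) -> list:
    """Midpoint (floored) of each breakpoint uncertainty interval.

    This is the coordinate used by all downstream hotspot and association
    statistics. Terminal events yield a single midpoint.
    """
    points = []
    for iv in (event.bp_left, event.bp_right):
        if iv is not None:
            points.append((iv[0] + iv[1]) // 2)
    if not points and event.event_class not in WHOLE_CHROM:
        raise ValueError("event has no breakpoint interval")
    return points
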