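"""Compare called events against a simulation truth set.

A planted event is recovered when a called event of the same isolate,
chromosome and class overlaps it reciprocally by at least half (intersection
over each span). Recall is the recovered fraction of planted events;
false-discovery is the fraction of calls matching no planted event. Both can
be restricted to events supported by a minimum number of SNP markers.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import GenomeMap
from .stats import rate_ci


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def _reciprocal(a, b, min_frac=0.5) -> bool:
    ov = _overlap(a.start, a.end, b.start, b.end)
    return (ov >= min_frac * (a.end - a.start + 1)
            and ov >= min_frac * (b.end - b.start + 1))


def _snps_spanned(genome: GenomeMap, chrom: str, start: int, end: int) -> int:
    pos = genome.snp_positions(chrom)
    return int(np.searchsorted(pos, end, "right") - np.searchsorted(pos, start, "left"))


@dataclass
class MatchResult:
    n_truth: int
    n_called: int
    n_recovered: int
    n_false: int
    pairs: list          # (planted, called)

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_truth if self.n_truth else float("nan")

    @property
    def fdr(self) -> float:
        return self.n_false / self.n_called if self.n_called else 0.0


def match_events(truth_events: list, called_events: list, genome: GenomeMap,
                 min_snps: int = 0, min_frac: float = 0.5,
                 classes=None) -> MatchResult:
    """Greedy one-to-one matching of planted and called events.

    Spans are clipped to the marker-covered part of the genome before the
    overlap test (calls can never extend past the outermost SNP of a tract).
    ``min_snps`` restricts both sides to events whose span holds at least
    that many markers; ``classes`` optionally restricts the event classes
    considered.
    """
    def keep(e):
        if classes is not None and e.event_class not in classes:
            return False
        return _snps_spanned(genome, e.chromosome, e.start, e.end) >= min_snps

    def clipped(e):
        pos = genome.snp_positions(e.chromosome)
        i = np.searchsorted(pos, e.start, "left")
        j = np.searchsorted(pos, e.end, "right") - 1
        if j < i:
            return (e.start, e.end)
        return (int(pos[i]), int(pos[j]))

    truth = [e for e in truth_events if keep(e)]
    called = [e for e in called_events if keep(e)]
    used = set()
    pairs = []
    for t in truth:
        t_lo, t_hi = clipped(t)
        for i, c in enumerate(called):
            if (i not in used and c.isolate_id == t.isolate_id
                    and c.chromosome == t.chromosome
                    and c.event_class == t.event_class):
                c_lo, c_hi = clipped(c)
                ov = _overlap(t_lo, t_hi, c_lo, c_hi)
                if (ov >= min_frac * (t_hi - t_lo + 1)
                        and ov >= min_frac * (c_hi - c_lo + 1)):
                    used.add(i)
                    pairs.append((t, c))
                    break
    return MatchResult(n_truth=len(truth), n_called=len(called),
                       n_recovered=len(pairs), n_false=len(called) - len(used),
                       pairs=pairs)


#: Table-style class -> the planted classes it aggregates
RATE_CLASS_MAP = {
    "I_LOH": ("I_LOH",), "T_LOH": ("T_LOH",), "I_DEL": ("I_DEL",),
    "I_DUP": ("I_DUP",), "T_DEL": ("T_DEL",), "T_DUP": ("T_DUP",),
    "aneuploidy_UPD": ("MONOSOMY", "TRISOMY", "TETRASOMY", "UPD"),
    "SNV": ("SNV",), "indel_complex": ("INDEL",),
}


def rate_recovery(called_events: list, mutations: list, truth,
                  design) -> dict:
    """Estimated per-class rates with CIs against the planted intensities.

    Returns {class: (RateEstimate, planted_rate, covered)} for the nine
    reported alteration classes; ``covered`` is True when the planted rate
    lies inside the estimate's 95% CI.
    """
    from .stats import class_counts
    counts = class_counts(called_events, mutations)
    N = design.total_divisions
    out = {}
    for label, members in RATE_CLASS_MAP.items():
        planted = sum(truth.rates.get(m, 0.0) for m in members)
        est = rate_ci(counts[label], N, label=label)
        covered = est.ci_low <= planted <= est.ci_high
        out[label] = (est, planted, covered)
    return out
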