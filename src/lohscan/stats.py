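"""Rate estimation and hypothesis tests for mutation-accumulation experiments.

Per-division rates are event counts divided by the total number of cell
divisions in the experiment, with exact (Garwood) Poisson confidence
intervals derived from chi-square quantiles:

    lower = qchisq(alpha/2, 2k) / 2          (0 when k = 0)
    upper = qchisq(1 - alpha/2, 2k + 2) / 2

both divided by N. These intervals are exact for a Poisson count and
conservative (coverage >= the nominal level).

Hotspot detection scans the genome in sliding windows and asks whether a
window holds more breakpoints than its length share predicts. With ~350
breakpoints over ~12 Mb the expected count per 65-kb window is ~2, far too
small for the Pearson chi-square approximation, so each window is tested
with a two-sided exact binomial tail; the single-region chi-square test
(:func:`chisq_gof`) remains available for a priori regions and whole
chromosomes, where the approximation is sound.
"""
from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .model import (
    AssociationResult, EventCall, ExperimentDesign, GenomeMap, HotspotWindow,
    MutationCall, RateEstimate, WHOLE_CHROM,
)

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 65_000
DEFAULT_STEP = 10_000

#: Wild-type per-division rates (x1, not x1e-3) of the reference strain, used
#: for fold comparisons in Table-style reports.
WT_REFERENCE_RATES = {
    "I_LOH": 3.3e-3, "T_LOH": 1.3e-3, "I_DEL": 0.1e-3, "I_DUP": 0.03e-3,
    "T_DEL": 0.02e-3, "T_DUP": 0.01e-3, "aneuploidy_UPD": 0.06e-3,
    "SNV": 4.8e-3, "indel_complex": 0.27e-3,
}

TABLE_CLASSES = list(WT_REFERENCE_RATES)


def round_sig(x: float, digits: int = 2) -> float:
    """Round to ``digits`` significant figures (0 stays 0)."""
    if x == 0 or not np.isfinite(x):
        return x
    return float(f"{x:.{digits}g}")


def printed(x: float) -> float:
    """Round to table display precision: 2 decimals below 1, 1 decimal below
    10, integers above (the conventional resolution of rate tables)."""
    if not np.isfinite(x):
        return x
    a = abs(x)
    if a < 1:
        return round(x, 2)
    if a < 10:
        return round(x, 1)
    return float(round(x))


def rate_ci(k: int, N: float, alpha: float = 0.05, label: str = "",
            ref_rate: Optional[float] = None) -> RateEstimate:
    """Per-division rate k/N with an exact Poisson (Garwood) CI on the count.

    ``ref_rate``, when given, adds the fold change rate/ref_rate.
    """
    if N <= 0:
        raise ValueError("N must be > 0")
    if k < 0 or int(k) != k:
        raise ValueError("k must be a non-negative integer")
    k = int(k)
    lo = 0.0 if k == 0 else sps.chi2.ppf(alpha / 2, 2 * k) / 2
    hi = sps.chi2.ppf(1 - alpha / 2, 2 * k + 2) / 2
    rate = k / N
    fold = rate / ref_rate if ref_rate else None
    return RateEstimate(label=label, k=k, N=float(N), rate=rate,
                        ci_low=lo / N, ci_high=hi / N,
                        ref_rate=ref_rate, fold=fold)


def fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Two-sidedness sums hypergeometric probabilities no greater than that of
    the observed table. All-zero margins give p = 1.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    if a + b + c + d == 0:
        return 1.0
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def chisq_gof(observed, weights) -> tuple:
    """Pearson goodness-of-fit of counts against expected proportions.

    ``weights`` must sum to 1; expected = total * weight, all > 0. For a
    single-region enrichment question use two bins (inside, outside) with the
    region's length share as the first weight.
    """
    obs = np.asarray(observed, dtype=float)
    w = np.asarray(weights, dtype=float)
    if obs.shape != w.shape:
        raise ValueError("observed and weights must have the same length")
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    total = obs.sum()
    if total <= 0:
        raise ValueError("observed total must be > 0")
    expected = total * w
    if (expected <= 0).any():
        raise ValueError("zero expected count in a bin")
    stat = float(((obs - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(stat, len(obs) - 1))
    return stat, p


def region_chisq(breakpoints, genome: GenomeMap, chrom: str,
                 start: Optional[int] = None, end: Optional[int] = None) -> tuple:
    """Two-bin chi-square for one region (or a whole chromosome) vs the rest.

    This is the single-region test appropriate for an a priori hypothesis
    such as a named hotspot interval or a candidate cold chromosome.
    """
    bp = _as_breakpoint_frame(breakpoints)
    c = genome.chromosome(chrom)
    if start is None:
        start, end = 1, c.length
    inside = int(((bp["chrom"] == chrom) & (bp["pos"] >= start) & (bp["pos"] <= end)).sum())
    share = (end - start + 1) / genome.genome_length
    return chisq_gof([inside, len(bp) - inside], [share, 1 - share])


def _as_breakpoint_frame(breakpoints) -> pd.DataFrame:
    if isinstance(breakpoints, pd.DataFrame):
        return breakpoints[["chrom", "pos"]]
    return pd.DataFrame(breakpoints, columns=["chrom", "pos"])


def _binom_two_sided(k: np.ndarray, n: int, p: float) -> np.ndarray:
    lo = sps.binom.cdf(k, n, p)
    hi = sps.binom.sf(k - 1, n, p)
    return np.minimum(1.0, 2 * np.minimum(lo, hi))


def hotspot_scan(breakpoints, genome: GenomeMap, window: int = DEFAULT_WINDOW,
                 step: int = DEFAULT_STEP, alpha: float = 0.05,
                 q_threshold: Optional[float] = None) -> tuple:
    """Sliding-window scan for breakpoint hotspots.

    Each window's count is compared with its length share of the genome by a
    two-sided exact binomial test; Benjamini-Hochberg correction is applied
    across all windows, and overlapping windows significant at
    ``q_threshold`` (default ``alpha``) on the enriched side are merged into
    maximal regions. A chromosome shorter than the window is tested as a
    single bin.

    Returns ``(windows, merged_regions)`` where ``merged_regions`` is a list
    of ``(chrom, start, end)``.
    """
    bp = _as_breakpoint_frame(breakpoints)
    n_total = len(bp)
    if n_total < 1:
        raise ValueError("need at least one breakpoint")
    G = genome.genome_length
    windows = []
    counts = []
    for c in genome.chromosomes:
        pos = np.sort(bp.loc[bp["chrom"] == c.name, "pos"].to_numpy())
        if window >= c.length:
            starts = np.array([1]); ends = np.array([c.length])
        else:
            starts = np.arange(1, c.length - window + 2, step)
            ends = starts + window - 1
        cnt = (np.searchsorted(pos, ends, "right")
               - np.searchsorted(pos, starts, "left"))
        counts.append(cnt)
        for s, e, k in zip(starts, ends, cnt):
            windows.append((c.name, int(s), int(e), int(k)))
    cnt_all = np.concatenate(counts)
    shares = np.array([(e - s + 1) / G for _, s, e, _ in windows])
    pvals = _binom_two_sided(cnt_all, n_total, shares)
    expected = n_total * shares
    qvals = multipletests(pvals, alpha, method="fdr_bh")[1]

    out = [HotspotWindow(chrom, s, e, k, float(exp),
                         stat=float((k - exp) ** 2 / exp), p=float(p), q=float(q))
           for (chrom, s, e, k), exp, p, q in zip(windows, expected, pvals, qvals)]

    thr = alpha if q_threshold is None else q_threshold
    sig = [w for w in out if w.q < thr and w.observed > w.expected]
    merged = []
    for w in sorted(sig, key=lambda w: (w.chromosome, w.start)):
        if merged and merged[-1][0] == w.chromosome and w.start <= merged[-1][2] + 1:
            merged[-1][2] = max(merged[-1][2], w.end)
        else:
            merged.append([w.chromosome, w.start, w.end])
    return out, [tuple(m) for m in merged]


def poisson_two_rate(k1: int, N1: float, k2: int, N2: float) -> float:
    """Exact conditional test that two Poisson processes share one rate.

    Conditional on the total, k1 ~ Binomial(k1 + k2, N1/(N1 + N2)); the
    two-sided p doubles the smaller tail (capped at 1). k1 + k2 = 0 gives 1.
    """
    if k1 < 0 or k2 < 0:
        raise ValueError("counts must be non-negative")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("divisions must be positive")
    n = k1 + k2
    if n == 0:
        return 1.0
    p = N1 / (N1 + N2)
    lo = sps.binom.cdf(k1, n, p)
    hi = sps.binom.sf(k1 - 1, n, p)
    return float(min(1.0, 2 * min(lo, hi)))


def mann_whitney(x, y) -> tuple:
    """Mann-Whitney U with two-sided p.

    Exact null distribution when min(n, m) <= 8 and there are no ties;
    otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, float); y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone in the raw p-values)."""
    return multipletests(np.asarray(pvals, float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# permutation association
# ---------------------------------------------------------------------------

def _interval_membership(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Boolean membership of positions in merged, sorted intervals."""
    if len(starts) == 0:
        return np.zeros(pos.shape, bool)
    idx = np.searchsorted(starts, pos, "right") - 1
    ok = idx >= 0
    idx = np.clip(idx, 0, None)
    return ok & (ends[idx] >= pos)


def _merged_track(genome: GenomeMap, track: str) -> dict:
    tr = genome.track(track)
    if len(tr) == 0:
        raise ValueError(f"feature track {track!r} is empty")
    per_chrom = {}
    for chrom, grp in tr.groupby("chrom"):
        ivs = sorted(zip(grp["start"], grp["end"]))
        merged = []
        for s, e in ivs:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        per_chrom[chrom] = (np.array([m[0] for m in merged]),
                            np.array([m[1] for m in merged]))
    return per_chrom


def feature_association(breakpoints, genome: GenomeMap, tracks,
                        n_perm: int = 10_000, seed: int = 0) -> list:
    """Permutation test of breakpoint overlap with feature tracks.

    The null re-places each breakpoint uniformly within its own chromosome
    (preserving per-chromosome event intensity) ``n_perm`` times. The
    empirical two-sided p counts permutations whose overlap is at least as
    far from the permutation mean as the observed overlap, with the +1
    correction, so p lies in [1/(n_perm + 1), 1]. Benjamini-Hochberg
    adjustment is applied across tracks.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if isinstance(tracks, str):
        tracks = [tracks]
    bp = _as_breakpoint_frame(breakpoints)
    rng = np.random.default_rng(seed)
    lengths = genome.chrom_lengths
    chrom_groups = {c: grp["pos"].to_numpy() for c, grp in bp.groupby("chrom")}

    results = []
    for track in tracks:
        merged = _merged_track(genome, track)
        observed = 0
        perm_counts = np.zeros(n_perm, int)
        for chrom, pos in chrom_groups.items():
            starts, ends = merged.get(chrom, (np.array([]), np.array([])))
            observed += int(_interval_membership(pos, starts, ends).sum())
            sim = rng.integers(1, lengths[chrom] + 1, size=(n_perm, len(pos)))
            perm_counts += _interval_membership(sim, starts, ends).sum(axis=1)
        mean = float(perm_counts.mean())
        extreme = int((np.abs(perm_counts - mean) >= abs(observed - mean)).sum())
        p = (1 + extreme) / (n_perm + 1)
        results.append(AssociationResult(
            track=track, observed=observed, perm_mean=mean, p=float(p),
            q=float("nan"), direction="over" if observed >= mean else "under"))
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


# ---------------------------------------------------------------------------
# Table-style rate report
# ---------------------------------------------------------------------------

def class_counts(events: list, mutations: list) -> dict:
    """Aggregate events/mutations into the nine reported alteration classes."""
    counts = {c: 0 for c in TABLE_CLASSES}
    for e in events:
        if e.event_class in counts:
            counts[e.event_class] += 1
        elif e.event_class in WHOLE_CHROM:
            counts["aneuploidy_UPD"] += 1
        # OTHER events are reported separately, not in the table
    for m in mutations:
        if m.kind == "SNV":
            counts["SNV"] += 1
        else:
            counts["indel_complex"] += 1
    return counts


def rate_table(events: list, mutations: list, design: ExperimentDesign,
               reference_rates: Optional[dict] = None,
               reference_counts: Optional[dict] = None,
               alpha: float = 0.05) -> pd.DataFrame:
    """Per-class counts, rates with exact CIs, folds and Fisher comparisons.

    ``reference_rates`` maps class label to the reference per-division rate
    (fold column); ``reference_counts`` maps label to ``(k_ref, N_ref)`` for
    Fisher exact comparisons of the two count/division pairs. Printed-
    precision columns round rate and reference to two significant figures
    before taking the fold, matching how such tables are conventionally
    displayed.
    """
    counts = class_counts(events, mutations)
    N = design.total_divisions
    if reference_rates is None:
        log.warning("no reference rates supplied; fold column omitted")
        reference_rates = {}
    rows = []
    for label in TABLE_CLASSES:
        k = counts[label]
        ref = reference_rates.get(label)
        est = rate_ci(k, N, alpha=alpha, label=label, ref_rate=ref)
        row = {
            "class": label, "k": k, "N": N,
            "rate": est.rate, "ci_low": est.ci_low, "ci_high": est.ci_high,
            "rate_e3": est.rate * 1e3,
            "rate_printed": printed(est.rate * 1e3),
            "ci_low_printed": printed(est.ci_low * 1e3),
            "ci_high_printed": printed(est.ci_high * 1e3),
            "fold": est.fold,
            "fold_printed": (printed(printed(est.rate * 1e3) / printed(ref * 1e3))
                             if ref else None),
        }
        if reference_counts and label in reference_counts:
            k_ref, n_ref = reference_counts[label]
            row["fisher_p"] = fisher_2x2(k, int(round(N)) - k,
                                         k_ref, int(round(n_ref)) - k_ref)
        else:
            row["fisher_p"] = None
        rows.append(row)
    return pd.DataFrame(rows)
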