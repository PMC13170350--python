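"""Relative coverage (RC) and per-allele copy-number binning.

A SNP's RC is its allele depth divided by the mean total depth over all SNPs
in the genome. At the heterozygous diploid baseline each parental allele sits
near RC 0.5; a duplicated allele near 1; a deleted allele at 0. Binning the
median-smoothed RC at the quarter-points between those levels (0.25, 0.75,
1.25, 1.75) yields integer per-allele copies 0..4.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import GenomeMap, IsolateProfile

DEFAULT_EDGES = (0.25, 0.75, 1.25, 1.75)
DEFAULT_WINDOW = 5
DEFAULT_MIN_DEPTH = 4


@dataclass
class CopyTrack:
    """Per-SNP RC values and (after binning) integer copy calls."""
    isolate_id: str
    data: pd.DataFrame  # chrom, pos, depth_total, rc_P1, rc_P2 [, c_P1, c_P2, masked]
    mean_depth: float
    params: dict = field(default_factory=dict)

    @property
    def binned(self) -> bool:
        return "c_P1" in self.data.columns


def compute_rc(profile: IsolateProfile, genome: GenomeMap) -> CopyTrack:
    """Convert allele depths to relative coverage.

    RC for allele j at SNP i is ``depth_j(i) / D`` where ``D`` is the mean of
    (depth_P1 + depth_P2) over all SNPs in the genome, so a fully heterozygous
    euploid profile has mean per-allele RC near 0.5. Rejects profiles with
    zero mean depth. RC is invariant to uniform depth scaling.
    """
    d = profile.depths
    total = (d["depth_P1"] + d["depth_P2"]).to_numpy(float)
    mean_depth = float(total.mean())
    if mean_depth <= 0:
        raise ValueError(f"isolate {profile.isolate_id}: mean SNP depth is zero")
    out = d[["chrom", "pos"]].copy()
    out["depth_total"] = total.astype(int)
    out["rc_P1"] = d["depth_P1"].to_numpy(float) / mean_depth
    out["rc_P2"] = d["depth_P2"].to_numpy(float) / mean_depth
    return CopyTrack(profile.isolate_id, out, mean_depth)


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    if window == 1 or len(x) == 0:
        return x.astype(float)
    # centered rolling median, shrinking toward the ends
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).median().to_numpy()
    )


def bin_rc(rc: np.ndarray, edges=DEFAULT_EDGES) -> np.ndarray:
    """Map RC to integer copies: rc < edges[0] -> 0, ..., rc >= edges[-1] -> len(edges)."""
    return np.searchsorted(np.asarray(edges), rc, side="right").astype(int)


def smooth_and_bin(track: CopyTrack, window: int = DEFAULT_WINDOW,
                   edges=DEFAULT_EDGES, min_depth: int = DEFAULT_MIN_DEPTH) -> CopyTrack:
    """Median-smooth RC per chromosome and bin into integer copies.

    SNPs with total depth below ``min_depth`` are masked (no copy call) rather
    than imputed, so isolated low-coverage SNPs cannot produce spurious
    single-marker deletions. Smoothing is a centered running median over
    ``window`` unmasked SNPs (odd, default 5), shrinking at chromosome ends;
    ``window=1`` is the identity. Binning is monotone in RC.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    data = track.data.copy()
    masked = data["depth_total"].to_numpy() < min_depth
    c1 = np.zeros(len(data), int)
    c2 = np.zeros(len(data), int)
    s1 = data["rc_P1"].to_numpy(float).copy()
    s2 = data["rc_P2"].to_numpy(float).copy()
    for _, idx in data.groupby("chrom", sort=False).indices.items():
        keep = idx[~masked[idx]]
        if len(keep) == 0:
            continue
        s1[keep] = _running_median(s1[keep], window)
        s2[keep] = _running_median(s2[keep], window)
        c1[keep] = bin_rc(s1[keep], edges)
        c2[keep] = bin_rc(s2[keep], edges)
    data["rc_P1"], data["rc_P2"] = s1, s2
    data["c_P1"], data["c_P2"] = c1, c2
    data["masked"] = masked
    params = dict(track.params, window=window, edges=tuple(edges), min_depth=min_depth)
    return CopyTrack(track.isolate_id, data, track.mean_depth, params)


def write_track(track: CopyTrack, path: str) -> None:
    """Dump the RC/copy track as TSV (for dot-plot style visualisation)."""
    track.data.to_csv(path, sep="\t", index=False)
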