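"""Shared domain types for hybrid-diploid genome-alteration analysis.

Coordinates are 1-based inclusive throughout (SGD convention); BED input and
output convert at the I/O boundary. The two parental genomes are labeled
generically ``P1`` and ``P2``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

EVENT_CLASSES = (
    "I_LOH", "T_LOH", "I_DEL", "I_DUP", "T_DEL", "T_DUP",
    "MONOSOMY", "TRISOMY", "TETRASOMY", "UPD", "OTHER",
)
INTERSTITIAL = {"I_LOH", "I_DEL", "I_DUP"}
TERMINAL = {"T_LOH", "T_DEL", "T_DUP"}
WHOLE_CHROM = {"MONOSOMY", "TRISOMY", "TETRASOMY", "UPD"}

SUBSTITUTION_CLASSES = (
    "A:T>T:A", "A:T>C:G", "A:T>G:C", "G:C>A:T", "G:C>C:G", "G:C>T:A",
)
INDEL_CONTEXTS = ("mononucleotide_run", "microsatellite", "direct_repeat_flank", "other")


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    cen_start: int
    cen_end: int

    def __post_init__(self):
        if not (1 <= self.cen_start <= self.cen_end <= self.length):
            raise ValueError(
                f"centromere {self.cen_start}..{self.cen_end} outside "
                f"chromosome {self.name} (1..{self.length})"
            )


@dataclass(frozen=True)
class TandemArray:
    """A tandemly repeated locus collapsed to a single reference unit.

    ``ref_units`` is the number of unit copies present in the reference
    assembly; cellular copy number is estimated from read depth relative
    to the genome average (see :func:`lohscan.spectrum.array_copies`).
    """
    name: str
    chromosome: str
    start: int
    end: int
    unit_length: int
    ref_units: int

    def __post_init__(self):
        if self.unit_length <= 0:
            raise ValueError("unit_length must be > 0")
        if self.ref_units < 1:
            raise ValueError("ref_units must be >= 1")


class GenomeMap:
    """Chromosomes, heterozygous SNP markers, feature tracks and tandem arrays.

    Parameters
    ----------
    chromosomes:
        List of :class:`Chromosome` in karyotype order.
    snps:
        DataFrame with columns ``chrom, pos, allele_P1, allele_P2``; positions
        1-based, strictly increasing within each chromosome.
    features:
        DataFrame with columns ``track, chrom, start, end, label`` (1-based
        inclusive intervals). ``label`` carries the repeat family for repeat
        tracks and is empty otherwise.
    arrays:
        Tandem arrays (rDNA-like, CUP1-like).
    """

    def __init__(self, chromosomes, snps: pd.DataFrame, features: Optional[pd.DataFrame] = None,
                 arrays: Optional[list] = None):
        self.chromosomes = list(chromosomes)
        self.snps = snps.reset_index(drop=True)
        if features is None:
            features = pd.DataFrame(columns=["track", "chrom", "start", "end", "label"])
        self.features = features.reset_index(drop=True)
        self.arrays = list(arrays or [])
        self._validate()
        self._snp_pos = {
            c.name: self.snps.loc[self.snps["chrom"] == c.name, "pos"].to_numpy()
            for c in self.chromosomes
        }

    # -- derived accessors -------------------------------------------------
    @property
    def chrom_names(self) -> list:
        return [c.name for c in self.chromosomes]

    @property
    def chrom_lengths(self) -> dict:
        return {c.name: c.length for c in self.chromosomes}

    @property
    def genome_length(self) -> int:
        return int(sum(c.length for c in self.chromosomes))

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def snp_positions(self, chrom: str) -> np.ndarray:
        return self._snp_pos[chrom]

    def n_snps(self) -> int:
        return len(self.snps)

    def track(self, name: str) -> pd.DataFrame:
        return self.features[self.features["track"] == name]

    # -- validation --------------------------------------------------------
    def _validate(self):
        lengths = self.chrom_lengths
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            if chrom not in lengths:
                raise ValueError(f"SNP on unknown chromosome {chrom!r}")
            pos = grp["pos"].to_numpy()
            if (pos < 1).any() or (pos > lengths[chrom]).any():
                bad = pos[(pos < 1) | (pos > lengths[chrom])][0]
                raise ValueError(f"SNP position {bad} outside {chrom} (1..{lengths[chrom]})")
            if (np.diff(pos) <= 0).any():
                bad = pos[1:][np.diff(pos) <= 0][0]
                raise ValueError(f"duplicate or unsorted SNP position {bad} on {chrom}")
        for _, row in self.features.iterrows():
            if row["chrom"] not in lengths:
                raise ValueError(f"feature on unknown chromosome {row['chrom']!r}")
            if not (1 <= row["start"] <= row["end"] <= lengths[row["chrom"]]):
                raise ValueError(
                    f"feature {row['track']} {row['chrom']}:{row['start']}-{row['end']} "
                    "outside chromosome"
                )
        for arr in self.arrays:
            if arr.chromosome not in lengths:
                raise ValueError(f"array {arr.name} on unknown chromosome")


@dataclass
class IsolateProfile:
    """Per-SNP allele-specific read depths for one sub-cultured isolate."""
    isolate_id: str
    cycles: int
    depths: pd.DataFrame  # chrom, pos, depth_P1, depth_P2 aligned to GenomeMap SNP order

    def __post_init__(self):
        d = self.depths
        if (d["depth_P1"] < 0).any() or (d["depth_P2"] < 0).any():
            raise ValueError(f"negative depth in isolate {self.isolate_id}")


@dataclass
class ExperimentDesign:
    """Isolates x sub-culture cycles and the cell-division denominator.

    ``total_divisions`` defaults to sum(cycles) * divisions_per_cycle; a study
    that states its own total (e.g. a printed denominator) may override it.
    """
    isolates: list  # of (isolate_id, cycles)
    divisions_per_cycle: float = 23.4
    total_divisions: Optional[float] = None

    def __post_init__(self):
        if self.total_divisions is None:
            self.total_divisions = float(
                sum(c for _, c in self.isolates) * self.divisions_per_cycle
            )
        if self.total_divisions <= 0:
            raise ValueError("total_divisions must be > 0")

    def divisions_for(self, isolate_id: str) -> float:
        for iid, cycles in self.isolates:
            if iid == isolate_id:
                return cycles * self.divisions_per_cycle
        raise KeyError(isolate_id)


def paper_design() -> ExperimentDesign:
    """The 46-isolate design: 38 isolates x 8 cycles + 8 x 20, 10,858 divisions."""
    isolates = [(f"iso{i:02d}", 8) for i in range(1, 39)]
    isolates += [(f"iso{i:02d}", 20) for i in range(39, 47)]
    return ExperimentDesign(isolates=isolates, divisions_per_cycle=23.4,
                            total_divisions=10858.0)


@dataclass
class EventCall:
    """One classified genome alteration.

    ``start``/``end`` are the first/last affected SNP positions. Breakpoint
    uncertainty intervals run from the nearest flanking baseline SNP to the
    first changed SNP; terminal and whole-chromosome events have no interval
    on the chromosome-end side.
    """
    isolate_id: str
    event_class: str
    chromosome: str
    start: int
    end: int
    bp_left: Optional[tuple] = None   # (flanking baseline SNP pos, first event SNP pos)
    bp_right: Optional[tuple] = None
    retained_parent: str = "none"     # P1 | P2 | none
    n_transitions: int = 0
    is_complex: bool = False
    n_snps: int = 0
    junction_repeat_family: Optional[str] = None
    large: bool = False
    event_id: Optional[str] = None
    state: Optional[tuple] = None   # (c_P1, c_P2) of the dominant tract

    def __post_init__(self):
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.event_class!r}")
        if self.end < self.start:
            raise ValueError("event end before start")

    @property
    def size(self) -> int:
        """Tract span in bp (1-based inclusive)."""
        return self.end - self.start + 1


@dataclass
class TranslocationCandidate:
    """A paired terminal deletion + duplication sharing a junction repeat family."""
    isolate_id: str
    del_event: EventCall
    dup_event: EventCall
    repeat_family: str


@dataclass
class MutationCall:
    isolate_id: str
    chromosome: str
    position: int
    kind: str                       # SNV | INDEL | COMPLEX
    ref: str
    alt: str
    substitution_class: Optional[str] = None
    context_class: Optional[str] = None
    context_seq: Optional[str] = None

    def __post_init__(self):
        if self.kind == "SNV" and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValueError("SNV must have 1-bp ref and alt")


@dataclass
class RateEstimate:
    """Per-division event rate with an exact 95% Poisson confidence interval."""
    label: str
    k: int
    N: float
    rate: float
    ci_low: float
    ci_high: float
    ref_rate: Optional[float] = None
    fold: Optional[float] = None

    def __post_init__(self):
        if not (0 <= self.ci_low <= self.rate <= self.ci_high):
            raise ValueError(f"inconsistent CI for {self.label}: "
                             f"{self.ci_low} <= {self.rate} <= {self.ci_high}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Tract:
    """Maximal run of SNPs with constant unmasked copy state."""
    chromosome: str
    i_first: int      # index into the chromosome's SNP array
    i_last: int
    pos_first: int
    pos_last: int
    c_P1: int
    c_P2: int
    n_snps: int

    @property
    def state(self) -> tuple:
        return (self.c_P1, self.c_P2)


@dataclass
class HotspotWindow:
    chromosome: str
    start: int
    end: int
    observed: int
    expected: float
    stat: float
    p: float
    q: float = float("nan")


@dataclass
class AssociationResult:
    track: str
    observed: int
    perm_mean: float
    p: float
    q: float
    direction: str  # over | under
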