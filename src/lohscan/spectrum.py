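"""Mutation spectrum, indel context, tandem-array copy number, telomere runs.

Base substitutions are folded onto the six complementary pairs (e.g. both
A>T and T>A belong to A:T>T:A). Per-bp rates use a diploid denominator:
rate = count / (divisions x 2 x genome length), since a diploid genome
presents two base pairs per reference position.
"""
from __future__ import annotations

import re
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    ExperimentDesign, GenomeMap, MutationCall, TandemArray, SUBSTITUTION_CLASSES,
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
RUN_MIN = 4          # bp; shortest mononucleotide tract (counting the indel allele)
MICROSAT_UNIT = (2, 6)
MICROSAT_MIN_UNITS = 3
DIRECT_REPEAT_MIN = 3


def classify_substitution(ref: str, alt: str) -> str:
    """Map one of the 12 ordered substitutions to its complementary pair class."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"not a DNA base: {ref!r}/{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref in "TC":  # normalise so the reference base is a purine
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    pair = {"A": "A:T", "G": "G:C"}[ref]
    alt_pair = f"{alt}:{_COMPLEMENT[alt]}"
    cls = f"{pair}>{alt_pair}"
    assert cls in SUBSTITUTION_CLASSES, cls
    return cls


def spectrum_table(mutations: list, design: ExperimentDesign,
                   genome: GenomeMap) -> pd.DataFrame:
    """Counts, proportions and per-bp per-division rates by substitution class.

    Only SNV calls contribute. The rate denominator is
    ``total_divisions x 2 x genome length`` (diploid base pairs).
    """
    if design.total_divisions <= 0:
        raise ValueError("zero divisions")
    snvs = [m for m in mutations if m.kind == "SNV"]
    counts = {c: 0 for c in SUBSTITUTION_CLASSES}
    for m in snvs:
        cls = m.substitution_class or classify_substitution(m.ref, m.alt)
        counts[cls] += 1
    total = sum(counts.values())
    denom = design.total_divisions * 2 * genome.genome_length
    rows = [
        {"class": c, "count": n,
         "proportion": (n / total) if total else 0.0,
         "rate_per_bp_per_division": n / denom}
        for c, n in counts.items()
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# indel context
# ---------------------------------------------------------------------------

def _indel_delta(ref: str, alt: str) -> tuple:
    """Return (kind, changed sequence) for a simple indel, trimming the shared prefix."""
    ref, alt = ref.upper(), alt.upper()
    if len(ref) == len(alt):
        raise ValueError("not an indel (ref and alt same length)")
    short, long_ = (ref, alt) if len(ref) < len(alt) else (alt, ref)
    if not long_.startswith(short):
        raise ValueError("unsupported indel representation (no shared prefix)")
    kind = "insertion" if len(alt) > len(ref) else "deletion"
    return kind, long_[len(short):]


def _in_mononucleotide_run(window: str, pos: int, delta: str, run_min: int) -> bool:
    if len(set(delta)) != 1:
        return False
    base = delta[0]
    left = pos
    while left > 0 and window[left - 1] == base:
        left -= 1
    right = pos
    while right < len(window) and window[right] == base:
        right += 1
    # the run length counts the indel allele itself
    return (right - left) + len(delta) >= run_min or (right - left) >= run_min


def _in_microsatellite(window: str, pos: int, delta: str) -> bool:
    lo, hi = MICROSAT_UNIT
    for unit_len in range(lo, hi + 1):
        pat = re.compile(r"(.{%d})\1{%d,}" % (unit_len, MICROSAT_MIN_UNITS - 1))
        for m in pat.finditer(window):
            if len(set(m.group(1))) == 1:
                continue  # a mononucleotide run repeated, not a microsatellite
            if m.start() <= pos <= m.end():
                return True
    return False


def _direct_repeat_flanked(window: str, pos: int, delta: str) -> bool:
    if len(delta) < DIRECT_REPEAT_MIN:
        return False
    # the changed sequence is a copy of nearby sequence (slippage between
    # direct repeats): it must occur in the window outside its own site
    occupied = set(range(pos, pos + len(delta)))
    for m in re.finditer(re.escape(delta), window):
        if not occupied & set(range(m.start(), m.end())):
            return True
    return False


def indel_context(window: str, ref: str, alt: str,
                  indel_offset: Optional[int] = None,
                  run_min: int = RUN_MIN) -> str:
    """Classify an indel's sequence context.

    ``window`` is reference sequence (>= 20 bp) centred on the indel site;
    ``indel_offset`` locates the first changed base within the window
    (default: centre). Precedence: mononucleotide run, then microsatellite,
    then direct-repeat flank, then ``other`` — the categories are mutually
    exclusive.
    """
    window = window.upper()
    if not set(window) <= set("ACGT"):
        raise ValueError("window contains non-ACGT characters")
    if len(window) < 20:
        raise ValueError("window must be >= 20 bp")
    _, delta = _indel_delta(ref, alt)
    if len(window) < len(delta):
        raise ValueError("window shorter than the indel")
    pos = len(window) // 2 if indel_offset is None else indel_offset
    if _in_mononucleotide_run(window, pos, delta, run_min):
        return "mononucleotide_run"
    if _in_microsatellite(window, pos, delta):
        return "microsatellite"
    if _direct_repeat_flanked(window, pos, delta):
        return "direct_repeat_flank"
    return "other"


# ---------------------------------------------------------------------------
# tandem arrays
# ---------------------------------------------------------------------------

def array_copies(mean_unit_depth: float, mean_genome_depth: float,
                 array: TandemArray) -> float:
    """Cellular copies of a tandem array per haploid genome.

    Reads from all cellular unit copies pile onto the ``ref_units`` collapsed
    units of the reference, so copies = depth ratio x ref_units. The ratio is
    taken against the diploid genome average, making the result per haploid
    genome; it is invariant to overall sequencing depth.
    """
    if mean_genome_depth <= 0:
        raise ValueError("mean genome depth must be > 0")
    if mean_unit_depth < 0:
        raise ValueError("unit depth must be >= 0")
    return (mean_unit_depth / mean_genome_depth) * array.ref_units


# ---------------------------------------------------------------------------
# telomere repeat runs
# ---------------------------------------------------------------------------

def telomere_run(seq: str) -> int:
    """Length of the maximal terminal TG1-3 repeat run.

    Parses the sequence suffix as a concatenation of units ``T G{1,3}``,
    permitting a truncated unit at the start of the run (reads beginning
    mid-repeat). Returns 0 when the suffix cannot start a unit.
    """
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    if not set(seq) <= set("ACGT"):
        raise ValueError("sequence contains non-ACGT characters")
    i = len(seq)
    while True:
        g = 0
        while g < 3 and i - g - 1 >= 0 and seq[i - g - 1] == "G":
            g += 1
        if 1 <= g <= 3 and i - g - 1 >= 0 and seq[i - g - 1] == "T":
            i -= g + 1      # a complete T G{1,3} unit
        else:
            i -= g          # trailing Gs form a truncated leading unit
            break
    return len(seq) - i
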