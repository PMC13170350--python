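"""Mutation spectrum, tandem-array copy number and telomere repeat runs."""
import lohscan as ls
from lohscan.model import MutationCall, paper_design
from lohscan.spectrum import (
    array_copies, indel_context, spectrum_table, telomere_run,
)
from lohscan.simulate import synthesize_terminal_reads

genome = ls.default_genome(scale=1.0, seed=1)
design = paper_design()

# --- substitution spectrum: 22 of 89 SNVs are A:T>T:A transversions
muts = [MutationCall("i", "chrI", 1, "SNV", "A", "T")] * 22
muts += [MutationCall("i", "chrI", 1, "SNV", "G", "A")] * 67
tbl = spectrum_table(muts, design, genome).set_index("class")
row = tbl.loc["A:T>T:A"]
print(f"A:T>T:A: {row['count']} of 89 SNVs = {100 * row['proportion']:.0f}% "
      f"of substitutions,")
print(f"  per-bp rate {row['rate_per_bp_per_division']:.2e} per division "
      f"(diploid denominator: 2 x {genome.genome_length / 1e6:.2f} Mb)")

# --- indel sequence context
window = "GCGCGCTTAAAAAGCGCGCGC"
print(f"\n1-bp A deletion in {window!r}: "
      f"{indel_context(window, 'TA', 'T', indel_offset=9)}")

# --- rDNA copy number from read depth over the collapsed repeat unit
rdna = next(a for a in genome.arrays if a.name == "rDNA")
copies = array_copies(mean_unit_depth=67 * 40, mean_genome_depth=40, array=rdna)
print(f"\nrDNA unit depth 67x the genome average, {rdna.ref_units} reference "
      f"units -> {copies:.0f} copies per haploid genome")

# --- telomere TG1-3 repeat runs from terminal reads
reads = synthesize_terminal_reads(genome, mean_len=362, sd=25, seed=4)
lengths = [telomere_run(r["seq"]) for r in reads]
exact = sum(l == r["true_length"] for l, r in zip(lengths, reads))
print(f"\nmeasured TG1-3 runs on {len(reads)} chromosome ends: "
      f"mean {sum(lengths) / len(lengths):.0f} bp, "
      f"{exact}/{len(reads)} exactly recover the generated length")
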