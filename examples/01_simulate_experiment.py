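"""Generate a synthetic mutation-accumulation experiment with known truth.

Builds a hybrid-diploid genome map (~50,000 heterozygous SNPs at full scale;
here a 10% scale for speed), plants genome alterations at the default
per-division rates over the 46-isolate design, and synthesises allele-depth
profiles at 40x coverage.
"""
from collections import Counter

import lohscan as ls

genome = ls.default_genome(scale=0.1, seed=1)
truth = ls.plant_alterations(genome, seed=2)
profiles = ls.synthesize_profiles(genome, truth, depth=40, seed=3)

print(f"genome: {len(genome.chromosomes)} chromosomes, "
      f"{genome.n_snps():,} SNP markers, {genome.genome_length / 1e6:.2f} Mb")
print(f"profiles: {len(profiles)} isolates x {genome.n_snps():,} SNPs at 40x\n")

counts = Counter(e.event_class for e in truth.events)
print("planted events by class (one experiment draw):")
for cls, n in sorted(counts.items()):
    print(f"  {cls:10s} {n:4d}")
print(f"  mutations  {len(truth.mutations):4d}")

# Each class count is a Poisson draw of rate x 10,858 cell divisions, so the
# totals fluctuate around the planting intensities from one seed to the next.
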