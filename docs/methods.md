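# Methods

This note documents the models, defaults and design choices behind
`lohscan`, and what the synthetic experiments do and do not establish about
real data.

## Input model and coordinates

The pipeline starts from per-SNP allele-specific read depths of a hybrid
diploid — the summary a variant caller produces from aligned reads — not
from raw FASTQ/BAM. Upstream alignment, genotyping and site filtering are
out of scope and must be done with standard tools; this boundary is stated
here because filtering choices upstream affect the depth tables the caller
sees. Coordinates are 1-based inclusive everywhere inside the package (SGD
convention); BED input/output converts exactly at the boundary
((start0, end0) = (start−1, end)). Parental genomes are labelled P1/P2;
the mapping to actual strain names is the caller's configuration, not the
library's concern.

## Relative coverage and copy binning

RC per allele is depth over the genome-wide mean total SNP depth, so a
heterozygous euploid marker sits near (0.5, 0.5). Normalisation is
genome-wide, matching the definition of RC against the average over all
SNPs; in a heavily aneuploid isolate this shifts all RC values by a few
percent, which the quarter-point bins absorb (an isolate whose median copy
sum deviates from 2 would warrant inspection). Bin edges (0.25, 0.75, 1.25,
1.75) are the symmetric maximum-margin separators of the expected RC levels
0, 0.5, 1.0, 1.5, 2.0; values ≥1.75 bin to copy 4.

Smoothing is a centred running median over 5 SNPs per allele per
chromosome, shrinking at ends. A median (not mean) is robust to isolated
counting noise and erodes true breakpoints by at most (window−1)/2 markers,
which stays inside the reported breakpoint uncertainty interval. SNPs with
total depth < 4 reads are masked, never imputed: a missing marker cannot
then masquerade as a two-allele deletion. Masked markers do not break a
tract when the flanking states agree.

## Event calling

Segmentation partitions unmasked markers into maximal constant-state runs.
Before classification, non-baseline tracts spanning fewer than `min_snps`
markers are treated as counting noise and removed, and equal-state
neighbours separated only by such noise are coalesced. This cleanup is what
lets a trisomic chromosome keep its whole-chromosome identity when a brief
depth excursion interrupts it. `min_snps` defaults to 5: at 40x coverage
the probability that an allele's Poisson depth crosses a bin edge is a few
percent per marker, and because the median filter correlates adjacent
smoothed values, three-marker excursions are common enough (tens per
46-isolate experiment, measured by simulation) to swamp the rare classes
(I_DUP in particular), while five-marker excursions are not. The threshold
is configurable; 3 reproduces the permissive behaviour.

Classification maps states to classes as in the README table. Terminal
means the tract reaches the first or last retained marker of the
chromosome; whole-chromosome means both. A terminal LOH spanning the
centromere is still T_LOH — only full first-to-last spans become
aneuploidy/UPD, because the class definitions are end-anchored. Unmapped
states (e.g. (3, 1)) are surfaced as class OTHER with the state attached,
never dropped.

Complex events: consecutive non-baseline tracts separated by baseline runs
shorter than 25 kb AND fewer than 100 markers merge into one event whose
transition count is the sum of its parts; the class is that of the largest
constituent, re-derived as terminal or whole-chromosome from the merged
span. An event is complex when its transitions exceed the simple count
(2 interstitial, 1 terminal, 0 whole-chromosome). The 25-kb distance sits
below the 65-kb hotspot scale so merging cannot manufacture hotspots; the
marker bound is set to ~the same physical scale at the ~241 bp mean marker
spacing (100 markers ≈ 25 kb), so the two conditions agree. Breakpoint
positions for all downstream statistics are the floored midpoints of the
uncertainty intervals (flanking unchanged marker, first changed marker).

Junction annotation requires every breakpoint interval of a DEL/DUP to
overlap repeat elements of one family (for terminal events, with another
element of that family elsewhere in the genome); per isolate, a T_DEL and a
T_DUP on different chromosomes sharing a family become one translocation
candidate. Confirming junctions at read level (split reads, long reads) is
out of scope.

## Rates and statistics

Rates are k/N with exact Garwood Poisson CIs; this is the construction that
reproduces all published intervals at printed precision, including the
asymmetric (0.06–0.81)×10⁻³ at k=3. Exact intervals are conservative
(coverage ≥ 95%). Fisher's exact test is two-sided by the sum of
hypergeometric probabilities ≤ the observed table's; the Mann-Whitney test
is exact (no ties, min(n,m) ≤ 8) or tie-corrected normal otherwise; the
two-rate Poisson test conditions on the total count and doubles the smaller
binomial tail. Display rounding in rate tables uses 2 decimals below 1,
1 decimal below 10, integers above; folds are ratios of displayed rates.

The hotspot scan slides a 65-kb window at a 10-kb step. Each window's count
is compared to its length share of the genome with a **two-sided exact
binomial** tail rather than the two-bin Pearson chi-square used for a
priori regions: with ~350 breakpoints over ~12 Mb the expected count per
window is ~2, where the chi-square approximation is badly anti-conservative
(measured: 46/100 uniform-null replicates show a spurious BH-significant
window with Pearson, 0/100 with the exact binomial, at identical 100/100
power on the 22-in-one-window configuration). The single-region chi-square
(`chisq_gof`, `region_chisq`) remains the right tool for a priori questions
— a named hotspot interval, a candidate cold chromosome — where expected
counts are adequate. BH-corrected q-values are reported per window and
overlapping enriched windows merge into maximal regions.

Feature association re-places each breakpoint uniformly within its own
chromosome (preserving per-chromosome intensity) and counts overlaps with a
feature track; the two-sided empirical p counts permuted overlaps at least
as far from the permutation mean as observed, with the +1 correction, so
p ∈ [1/(n_perm+1), 1]. With few breakpoints the overlap count is strongly
discrete and the p-values are conservative; they are valid, not uniform.
n_perm defaults to 10,000, seeded.

## Spectrum, arrays, telomeres

Substitutions fold onto six complementary pairs. Per-bp rates divide by
divisions × 2 × genome length — the diploid denominator, which is the
convention consistent with the published per-bp figures given the
per-division SNV rate and class shares. Indel context precedence is
mononucleotide run (≥ 4 bp counting the indel allele) → microsatellite
(unit 2–6 bp, ≥ 3 units) → direct-repeat flank (the changed sequence, ≥ 3 bp,
occurs again nearby in the window) → other; the categories are mutually
exclusive, matching how such counts are reported. The run-length threshold
is configurable since no standard value exists.

Tandem-array copies per haploid genome are (unit depth / genome depth) ×
reference units: reads from all cellular copies pile onto the collapsed
reference units, and taking the ratio against the diploid genome average
makes the result per haploid genome. Telomere runs are the maximal suffix
parseable as units T G₁₋₃, permitting a truncated leading unit (reads start
mid-repeat); a trailing bare T does not count. If the sequence 5' of the
run ends in G or T the run can be overestimated by that terminal partial
unit — the generator avoids this by construction, real subtelomeres need
not.

## The synthetic generator

The generator's defaults are the study conditions: 16 chromosomes at R64
lengths, ~50,000 markers (mean spacing ~241 bp), 46 isolates (38×8 + 8×20
sub-culture cycles) at 23.4 divisions per cycle giving the stated 10,858
total divisions (the per-cycle constant is configurable since its
derivation lives outside the main text), depth 40, and per-class planting
intensities equal to the observed counts over 10,858 — with the
aneuploidy/UPD block split by its observed composition (12 monosomy, 13
trisomy, 1 tetrasomy, 6 UPD).

Placement is uniform per bp with no intrinsic hotspots, so hotspot tests
have a clean null; power studies plant excess breakpoints in a stated
window. Interstitial LOH tract lengths are geometric with mean 10 kb — a
placeholder, since no empirical tract-length distribution is given — and
every planted tract must span at least 5 markers, the pipeline's stated
sensitivity floor, so recovery criteria measure the caller rather than the
tract-length tail. Terminal LOH breakpoints are uniform over arms.
DEL/DUPs join a sampled same-family repeat pair; cross-chromosome pairs are
planted as a translocation's reciprocal products (one T_DEL + one partner
T_DUP in the same isolate) at the mean of the two terminal rates, which is
the intensity the truth set records for both classes — the published 9 vs 8
terminal counts are one unpaired observation apart, consistent with paired
production. 21% of LOH events receive 1–2 short heterozygous gaps (3–6
markers) so they call as complex; every resulting segment keeps ≥ 5
markers. Events in one isolate are kept ≥ 26 kb apart (beyond the caller's
merge distance) so planted events stay distinct, relaxing only when a
small-scale genome is too crowded; overlaps are re-drawn. Depth noise is
Poisson with no overdispersion knob; SNV classes default to the observed
A:T>T:A share (22/89) with the remainder uniform; indel contexts default to
8/14 runs, 4/14 microsatellites, 2/14 direct-repeat. Per-isolate rDNA
copies are Normal(134, 15), CUP1 Normal(30, 5), telomere target lengths
Normal(362, 25) truncated at 0 — location parameters from the reported
medians, spreads chosen as plausible emulation knobs.

What passing tests show: the caller recovers what the generator plants
under Poisson counting noise at the study's design, the statistics are
calibrated on the generator's null, and the rate machinery reproduces the
published table exactly. What they do not show: robustness to GC/mappability
bias, overdispersed or correlated depth noise, mosaicism within a colony,
repeat-mediated mis-mapping, or upstream genotyping artefacts — none of
which the generator emulates.

## Problem sizes and determinism

The default test suite runs reduced problem sizes (genome scales 0.05–0.2)
for unit and property tests and one full-scale (scale 1) experiment plus
100-replicate scan calibrations in the acceptance tests, completing in
about a minute. All stochastic tests fix their seeds; every simulation API
threads a single integer seed, and the CLI records it (with a config hash)
in every output. The rate-CI coverage guarantee (≥ 93–95%) applies per
class; with nine classes per run, one class missing coverage in a given
draw is within expectation, which is why recovery asserts ≥ 8 of 9.
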