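# Methods

`ltrpop` analyses populations of centromere-specific *Gypsy* LTR
retrotransposons (the Cereba/Quinta type found in Triticeae centromeres):
it discovers full-length copies, dates their insertions, resolves their
subfamily structure, locates CENH3-binding hot spots, and asks whether
genetically similar copies sit at similar distances from the centromere
midpoint. Because the pipeline's accuracy can only be measured where the
truth is known, the package ships a first-class synthetic-genome
generator; every guarantee the test suite asserts is a statement about
the generator's study conditions, detailed below.

## Full-length copy discovery

A full-length element is defined operationally: two hits of the family
LTR consensus in the same orientation, whose span (5′ LTR start to 3′
LTR end) falls inside a family size window (7,700–8,000 bp for the
Cereba-type family; 4,300–4,500 and 4,700–4,800 bp for the two Quinta
length classes), with the family's internal coding region between them.

* **LTR hits.** Exact 16-mers of the LTR consensus are matched against
  the genome (both orientations), seed diagonals are clustered into
  candidate loci, and each locus is verified by infix edit-distance
  alignment. Defaults: identity ≥ 0.8 and coverage ≥ 0.8 of the LTR
  consensus. Hit boundaries are then polished by sliding the terminal
  30 bp of the consensus within ±6 bp and taking the offset with the
  most matches; edit-distance endpoints otherwise wobble by a few bases
  when terminal bases are mutated, which would corrupt TSD extraction.
  The polish never looks at the flanking duplication itself, so it
  cannot rescue a recombinant copy from the TSD filter.
* **CDS screen.** The inter-LTR region must carry the family internal
  consensus: a 16-mer seed-count quick reject followed by infix
  alignment at ≥ 0.70 identity. This removes LTR pairs found at the
  right distance by chance (the between-LTR sequence is then host DNA
  and shares essentially no 16-mers with a multi-kb consensus).
* **Overlap resolution.** Candidates are accepted greedily by combined
  LTR hit score, ties to the leftmost start — output is deterministic.
* **TSD filter.** The 5 bp immediately left and right of the element
  (read on the forward genomic strand regardless of element orientation)
  are the target-site duplication pair; copies whose TSDs differ at more
  than 1 position are removed as recombination/rearrangement suspects.
  Copies whose flank is truncated by a contig edge are also removed —
  their status cannot be confirmed. TSD length defaults to 5 bp, the
  canonical value for *Gypsy* integrases.

## Insertion dating

The two LTRs of a copy are identical at insertion. They are aligned
locally (match +5, mismatch −4, gap open 10, gap extend 0.5 — EMBOSS
Water conventions), transitions and transversions are counted over
ungapped columns (ambiguity codes excluded), and the divergence is
corrected with the Kimura two-parameter distance
d = −½·ln((1 − 2P − Q)·√(1 − 2Q)). The age is T = d / (2r) with
r = 1.3 × 10⁻⁸ substitutions/site/year (the accepted intergenic rate for
grasses); the factor 2 reflects that both LTRs diverge from their common
initial state. Saturated inputs (log argument ≤ 0) raise an explicit
error rather than returning NaN, and copies whose LTR alignment covers
less than 50% of the shorter LTR are rejected as undatable. A
99th-percentile filter is provided for display of age distributions.

Dating precision is counting-limited: a 1 kb LTR pair at 10 ky carries
only ~0.26 expected differences, so single-copy estimates at young ages
are dominated by shot noise and only cohort means are meaningful. The
validation cohorts are sized for a ≤ 5% relative standard error of the
mean (≈ 2,000 copies at 10 ky, ≈ 300 at 100 ky, ≈ 150 at 1 My).

## Alignment engine

All affine-gap alignment goes through Biopython's `PairwiseAligner`.
Full dynamic programming over two ~8 kb sequences costs seconds, which
is prohibitive across hundreds of copy-to-consensus alignments, so for
large near-identical inputs the engine chains unique shared 21-mers into
collinear anchors, runs the exact affine DP only on inter-anchor gaps,
extends into the tails with free-end-gap alignments, and trims the
result to its maximal-scoring local window (gap runs scored atomically
so the open penalty is charged once per run). For end-to-end homologous
inputs this attains the full Smith–Waterman optimum (asserted against
the full DP in the tests); with long unrelated flanks it can sit
marginally (< 1%) below the optimum because chance-match extensions need
not pass through an anchor boundary. Inputs under 10⁶ matrix cells
always use full DP.

A practical note the test suite encodes: with the Water gap penalties
(open 10, extend 0.5) the optimal local alignment of two sequences
sharing a core *does* extend into unrelated flanks — cheap gap extension
makes random-DNA alignment score-positive. Dating is therefore always
run on extracted LTR intervals, not on arbitrary windows.

## Variant calling and population structure

Each copy is aligned to the family consensus with heavy gap penalties
(open 50, extend 0.1) that keep near-identical copies colinear. The
alignment is collapsed into consensus coordinates: copy bases inside
insertions are discarded (they have no consensus coordinate), consensus
positions deleted in a copy are missing data, and positions outside the
locally aligned region are missing. Sites are retained when the
minor-allele frequency among non-missing calls is ≥ 1% (computed as
1 − max allele frequency, so multi-allelic sites are handled) and the
per-site missing fraction is ≤ 90%. The missing cutoff is applied per
site (the open design choice; a per-copy cutoff is subsumed by the
separate 30%-coverage rule that drops copies failing to align). Copies
aligning over < 30% of the consensus are dropped with a warning. Tables
are emitted as VCF 4.2 with the consensus as the contig and haploid
genotypes; the VCF round-trips losslessly.

The family consensus is built from 30 randomly sampled copies (seeded,
without replacement) by column majority over a multiple alignment.
The built-in MSA is a star alignment against the longest sampled copy
(each copy pairwise-aligned to the centre, columns merged, insertion
columns keyed by centre position) rather than a guide-tree progressive
aligner: for copies within a few percent of one another the two give the
same majority consensus, and the star form is deterministic and
dependency-free. An external `mafft` engine can be selected per call.
Majority-gap columns are dropped; base ties break alphabetically.

PCA encodes genotypes as allele indices, mean-imputes missing values per
site, centres, and uses a deterministic full SVD (scikit-learn, sign
convention: largest-magnitude loading positive). Pairwise SNP distances
count sites where both copies are non-missing and differ — the
pairwise-deletion convention of `ape::dist.gene`, against which the
implementation is cross-checked.

## CENH3 hot spots and coverage projection

Hot spots are maximal runs of ≥ 100 bp where experimental depth is both
≥ 5× the region-average baseline and ≥ 5× the per-base sum of all
control and mock tracks. Runs are strict: a single sub-threshold base
splits them (no gap tolerance — the open question resolved toward the
stricter reading). The baseline is computed once per region set, so
centromeres and a control arm are screened with their own averages; a
zero baseline is an explicit error. An optional `max_len` accommodates
screens that also bound peak size from above (off by default).

Peaks are assigned to a TE family by local alignment against a family
library on both strands, requiring ≥ 90 aligned columns at ≥ 70%
identity (identity = matches / alignment columns, the blastn
convention); ties go to higher identity, then alphabetical family.
Counts are normalised to peaks per Mb of annotated family sequence.

For consensus profiles, the per-base genomic depth over each copy is
transferred through its copy-to-consensus alignment: insertion bases
contribute nothing, deleted consensus columns receive nothing, and
minus-strand copies are projected in consensus orientation. Projection
conserves depth exactly (total projected = total genomic minus insertion
bases — asserted in tests). The experiment/mock ratio profile adds a
pseudocount of 1 to the denominator.

## Spatial association

A copy's position is its element-interval midpoint. The positional
difference between copies i and j is | |pᵢ − m| − |pⱼ − m| | in Mb,
where m is the centromere midpoint — a pseudometric (two copies
equidistant on opposite sides differ by zero). Association between this
matrix and the pairwise SNP matrix is tested with a Mantel test:
Spearman correlation over upper triangles, 9,999 joint row/column
permutations of one matrix, one-sided for positive association (the
hypothesis is that copies active at the same time inserted at similar
distances), p = (1 + #{r_perm ≥ r_obs}) / (permutations + 1) so p is
never exactly zero. Missing entries are dropped pairwise. When no
entries are missing, ranks are computed once and indexed under each
permutation (the permuted triangle is a fixed multiset), which makes
9,999 permutations cheap at n of a few hundred.

## The synthetic study

The generator emulates one chromosome (default 5 Mb) with a defined
centromere (1.5–3.5 Mb) and two families mirroring the real geometry:
a 7,850 bp element with 1,000 bp LTRs and a 4,400 bp element with 550 bp
LTRs. Background sequence is i.i.d. uniform A/C/G/T — discovery operates
on consensus similarity, not composition, so realistic base composition
is deliberately not modelled.

* **Mutation model.** Copies descend from one master lineage per family.
  A copy of age *a* inherits every master mutation event younger than
  *a* (shared, age-ordered differences from the present-day consensus)
  plus private per-site substitutions at probability r·a in each LTR and
  the internal region independently. Master LTR mutations are mirrored
  into both LTRs, so intra-copy LTR divergence comes from private
  mutations only, with expectation 2·r·a per site — exactly the dating
  model's assumption. The shared master history makes similar-aged
  copies genetically similar, which is the structure behind the
  age-vs-position Mantel signal; with purely private mutations, pairwise
  SNP distance would be independent of age difference and no spatial
  association could exist. Transitions are drawn with probability
  ts/tv ratio ÷ (ratio + 1) per event (default ratio 2).
* **Placement and ages.** Genuine copies (default 100 per family) and
  TSD-broken recombinant decoys are placed without overlap inside the
  centromere; solo-LTR and truncated decoys in the arms. With the
  age-position gradient on, age increases linearly in expectation with
  distance from the midpoint (multiplicative noise, σ = 8%), ages
  spanning 10 ky–2.5 My; subfamilies (default 3 per family, 20
  diagnostic internal sites each) are assigned by age era. Requested
  implants that cannot fit raise an explicit overflow error.
* **TSDs.** Each implant is flanked by an identical random 5-mer;
  recombinant decoys get a 3′ TSD broken at ≥ 2 positions.
* **ChIP tracks.** Integer per-base depth, Poisson. The experimental
  track carries 150 bp enrichment segments centred in the 5′ LTR of each
  genuine copy of the target family at fold × background (default
  30 × 10 reads/bp); control and mock are background-only at the same
  mean. The 30-fold default reflects that hot spots must clear both
  caller conditions — in particular ≥ 5× the *sum* of two background
  controls (~20 reads/bp) at every base of a ≥ 100 bp run; CENH3
  hot-spot contrasts of this magnitude are what the bespoke caller is
  designed for. With fold = 1 the experimental track is exchangeable
  with the controls and the caller returns nothing.
* **Determinism.** All randomness flows from `SeedSequence([seed, k])`
  children; identical seeds give byte-identical genomes, truth and
  tracks.

**What the generator does not model** — and therefore what passing tests
do not show about real data: nested insertions, segmental duplications
and tandem repeats (no repeat-induced false LTR pairs beyond the planted
decoys), read-mapping ambiguity in coverage tracks (depth is drawn, not
mapped, so multi-mapping artifacts over near-identical copies are
absent), indel mutations in elements (substitutions only; the aligners
are exercised on indels through constructed cases instead), base
composition and methylation-driven mutation-rate heterogeneity, and
inter-element recombination beyond a broken TSD. Real-genome recall and
precision will be lower than the synthetic figures; the synthetic runs
validate the machinery, not the difficulty of real centromeres.

## Numerical and design choices

* Internal coordinates are 0-based half-open; GFF3/VCF are written
  1-based per their standards; BED/bedGraph 0-based half-open.
* Match/mismatch scores +5/−4 (EMBOSS DNA defaults) wherever only gap
  penalties are prescribed.
* The two-parameter correction is used for dating with transitions and
  transversions distinguished; its domain is enforced (explicit
  saturation error).
* k-mer sizes: 16 for seeding/screening (4¹⁶ ≈ 4×10⁹ — chance genome
  hits are rare at 5 Mb), 21 for alignment anchors (uniqueness within a
  sequence pair).
* Greedy overlap resolution, alphabetical tie-breaks, seeded sampling
  and full-SVD PCA make every stage deterministic for a fixed seed; the
  run manifest records version, seeds, thresholds and stage counts.
* Desk-scale problem sizes used by the shipped analyses: 5 Mb genome,
  60–100 copies per family, 9,999 Mantel permutations. These are the
  generator's study conditions; scaling up changes runtimes, not
  semantics.

## Known limitations

* The anchored aligner is exact only when the optimal path crosses its
  anchors; highly diverged copies (> ~20%) fall back to full DP or fail
  with an explicit error rather than degrade silently.
* Solo LTRs and truncated copies are rejected, not catalogued; the
  package does not annotate them as first-class features.
* No confidence intervals on ages and no substitution-model selection.
* The hot-spot caller assumes integer, gap-free per-base tracks covering
  whole chromosomes.
* The Mantel test is one-sided for positive association by design.
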