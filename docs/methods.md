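# Methods

This note documents the statistical models, conventions and design choices
behind peppermap, and what the synthetic-data generators do and do not
emulate.

## SNP discovery

Genotypes are called per sample per site from base counts. A base whose
read fraction is **strictly greater than** `hom_fraction` (default 0.90) is
called homozygous — the correction for sequencing error in older consensus
callers; 9/10 reads is therefore *not* homozygous. Otherwise the two most
frequent bases are called heterozygous, subject to two guards the
homozygosity rule alone does not fix: any third base above a 1-read noise
floor, or a tie for the second allele, makes the call missing. Zero depth
is missing.

A site is a SNP when two samples are each homozygous with depth ≥
`min_depth` (default 3) for different alleles. Sites with more than two
alleles among qualifying homozygotes are dropped rather than decomposed:
the downstream assay is biallelic. The adjacency filter removes **both**
members of any pair ≤ `adjacency_window` (default 50, inclusive distance)
apart on a chromosome; the window is a guard zone for probe design, which
fails for either member, and the filter is idempotent.

Phenotype categorization applies the calling rule within each group's
samples separately: a SNP callable within blocky only, hot only, or within
both is assigned accordingly. A SNP polymorphic only *between* groups
(fixed within each) satisfies the rule in neither group and is excluded by
default; `cross_group_both=True` assigns such SNPs to "both" instead, since
the reading of "occurs within both" is genuinely ambiguous.

Gene annotation treats intervals as 1-based inclusive on both ends, and
requires non-overlapping genes per chromosome (the annotation is a
single-isoform gene table, not a transcript hierarchy).

## Array design

Flanks are `[pos−50, pos−1]` and `[pos+1, pos+50]`, truncated and flagged
at chromosome ends. Bead type I is assigned to the two same-channel allele
pairs {A,T} and {C,G}; everything else is type II. The commercial design
score is proprietary, so the score function is pluggable; the default
stand-in is flank completeness (1.0 for two full 50-base flanks), which is
deterministic, lives in [0, 1], and reflects the one design covariate the
simulation controls. The minor-allele rule is implemented in the literal
sample-count form — minor allele carried by ≥ 2 panel samples (2 of 22 ≈
9%) — with the allele-frequency form also computed and reported. Selection
among a gene's passing candidates is not specified anywhere, so a
deterministic convention is declared: highest design score, then highest
panel MAF, then smallest genomic position.

## Array QC

Call frequency = called/total samples; a marker calling zero samples is
"failed", all others "functional"; a functional marker is polymorphic when
≥ 2 distinct genotypes occur among called samples. MAF counts each
heterozygote allele once over 2 × called. The summary spectra use
disjoint-by-convention tiers: call frequency [0, 0.750), [0.750, 0.980),
[0.980, 0.999], exact 1.000; cluster score <0.2, [0.2, 0.3), [0.3, 0.6),
[0.6, 0.8), ≥0.8 (printed cluster-score tables usually show overlapping
"<" bounds; the disjoint reading is a convention); MAF in ten 0.05-wide
bins over [0, 0.5]. Threshold counts use strict inequality.

## F2 linkage mapping

**Recombination fraction.** For codominant markers the nine two-locus
genotype classes have probabilities (corners) (1−r)²/4 parental and r²/4
double-recombinant, (edges) r(1−r)/2, and (center, the phase-ambiguous
double heterozygote) ((1−r)² + r²)/2. `estimate_rf` maximizes this
multinomial likelihood by bounded scalar search on [0, 0.5] and checks the
boundary points, so identical vectors return exactly r = 0. The bulk path
`pairwise_rf` computes all pairs' class counts with indicator-matrix
products and iterates the standard EM (expected recombinant gametes over 2N
meioses; the center class contributes 2r²/((1−r)²+r²)); its fixed point is
the same MLE, and tests assert agreement with both the scalar search and an
independent 10⁻⁴ grid oracle. LOD = (ln L(r̂) − ln L(0.5))/ln 10.

**Grouping.** Single-linkage closure over edges with LOD ≥ `lod_min` and
r ≤ `r_max` (defaults 3.0 and 0.4), or a likelihood-ratio p-value mode
(χ², 1 df, α configurable). The LOD threshold must scale with the number
of marker pairs tested: at ~5500 markers there are ~1.5×10⁷ null pairs and
LOD 3 (p ≈ 10⁻⁴) would admit on the order of a thousand false edges, any
one of which merges two chromosomes under single linkage. The shipped
large-panel analyses therefore use LOD 10, a Bonferroni-scale stringency;
true adjacent markers at sub-cM spacing in 90 F2 carry LODs above 40, so
the partition is insensitive to the exact choice across roughly LOD 8–40.
Groups are numbered by size then lowest marker index for determinism.

**Ordering.** The objective is SARF (sum of adjacent recombination
fractions). Groups of ≤ 8 markers are solved exactly by enumeration (half
the permutations, fixing orientation). Larger groups start from a greedy
nearest-neighbour path grown from the tightest pair and improve with
best-move 2-opt (segment reversal; O(1) delta on a path) and single-marker
relocation until neither helps. Improvement requires a strict gain beyond
1e-15 and scans in fixed order, so results are deterministic. Orientation
is canonicalized by marker-id comparison of the endpoints, or by an
optional anchor marker expected in the first half of the group.

**Positions, bins, diagnostics.** Positions are cumulative Kosambi
distances of adjacent r̂ (d = 25·ln((1+2r)/(1−2r)) cM; inverse
r = ½·tanh(d/50); round-trip exact to 10⁻¹⁰). Adjacent markers join a
recombination bin when their genotypes agree at every individual called at
both (zero observed recombination) with at least `min_shared` shared
individuals; an identical-vector mode (same missing pattern required) is
also available — the two differ only in how missingness is treated, since
for codominant F2 genotypes any visible difference implies at least one
recombinant gamete. Double crossovers are counted per individual at
interior markers whose nearest non-missing flanks (within `flank_reach`
markers) agree with each other but not the middle; markers more than
`dco_sd_mult` SDs above the group mean are flagged. The published
workflows removed such markers by manual inspection of haplotype plots;
the SD rule is this package's reproducible stand-in. The heat-map quality
statistic is the mean over rows of the Spearman correlation between
|i−j| and r̂ — near 1 for a correct order.

**Translocation segments.** When a reciprocal translocation between the
parents makes one chromosome unorderable as a whole, its pieces are
ordered independently and concatenated; all adjacent distances, including
across the junction, are then computed on the fixed order with no
reordering. Map-to-map comparison normalizes positions per group to
[0, 1], matches groups by best reciprocal marker overlap, flips a group
when its shared markers run oppositely, and reports pooled R².

## Diversity analyses

A marker is monomorphic within a group when every *called* group sample is
homozygous for one shared allele; heterozygotes break the run because a
swept region in inbred material should be fixed, while missing calls carry
no evidence and are ignored (whether rare off-type calls should be
tolerated is unknowable from the published analysis; strict fixation is
the default). The block is the maximal such run through the marker nearest
the focal position; a polymorphic focal marker yields an empty block.

The Evanno table computes L(K) = mean lnP over replicates, first
differences L′, absolute second differences |L″|, and
ΔK = |L″(K)|/sd(lnP at K) with the sample (ddof = 1) standard deviation;
ΔK is undefined at boundary K and where sd = 0 (flagged). ΔK is invariant
to adding a constant to all lnP. Admixture inference itself is out of
scope; group labels are inputs, with a light allele-sharing hierarchical
clustering provided for closed-loop synthetic runs.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure* the pipeline's rules
operate on, not raw sequencing realism.

- **Panel pileups.** 22 samples in two phenotype groups of 11; true
  genotypes drawn per group under Hardy–Weinberg from planted frequencies;
  depth Poisson (default mean 20); each read carries one allele and is
  corrupted to a uniform other base with probability `error_rate` (default
  0.01). The pileup dialect is a simplified 6-column text (chrom, 1-based
  pos, ref, depth, base string, quality placeholder) carrying exactly the
  fields the discovery rules use; read qualities, mapping artifacts,
  indels and alignment are not modeled. Emission can be restricted to
  windows around planted SNPs, mirroring pileup generation against a
  position list; passing recovery tests on this input shows the *rules*
  are implemented correctly, not that the pipeline is robust to alignment
  error.
- **F2 meioses.** Gametes follow a Markov walk along the true marker
  order with switch probability inverse-Kosambi of the true adjacent
  distance — no crossover interference, matching the pairwise estimators
  being tested. A translocation is modeled as the donor chromosome's tail
  re-hung on the recipient's segregation frame at a configurable junction
  distance, with only balanced gametes transmitted; this reproduces the
  pseudolinkage phenomenon without cytogenetic detail (semi-sterility,
  unbalanced gametes and segregation distortion are not modeled, and the
  true transmission genetics of the study cross are not published).
- **Diversity panel.** Balding–Nichols group frequencies
  (Beta with mean p and variance scaled by F, default F_ST = 0.3 for
  divergent domesticated groups) around Uniform(0.05, 0.95) ancestral
  frequencies; Hardy–Weinberg within groups; uniform missingness (default
  0.8%, the error rate scale of array genotyping). The planted fixed
  region's flanking markers are forced polymorphic within the target group
  so that the planted block is exactly the maximal run by construction —
  without this, a flanking marker can drift to fixation by chance in a
  small group and legitimately extend the block.
- Missingness is uniform at random everywhere; no structured dropout.

## Problem sizes and numerical choices

The shipped analyses use: 1 Mb / 500 planted SNPs / 22 samples for
discovery recovery; 12 chromosomes × 460 markers × 90 F2 for map recovery
(the scale at which grouping stringency matters, see above); 60 markers ×
200 F2 for segment reassembly; 300 markers × 36 samples with a 23-marker
planted block for sweep detection. EM iterations cap at 200 with a 10⁻⁹
convergence tolerance; r is clipped to [10⁻⁹, 0.5] inside logs;
`kosambi_cM` raises at r ≥ 0.5 while internal position accumulation caps
r just below 0.5 for pairs estimated at independence. Ties in ordering
break toward the first-scanned move; group numbering, sample iteration
and site ordering are all sorted, so every output is reproducible
byte-for-byte for a fixed seed.

## Known limitations

- Pairwise (two-point) mapping only; no multipoint likelihood, so marker
  order within zero-recombination bins is arbitrary.
- The design score stand-in ranks candidates by flank completeness only;
  it reproduces the selection *logic*, not commercial scores.
- Cluster (GenTrain-style) scores are summarized, never computed.
- The ΔK criterion is implemented on supplied likelihood tables; no MCMC.
- Manufacturing attrition between a submitted manifest and a shipped
  array is an input list, not a model.
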