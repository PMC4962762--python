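# peppermap

SNP discovery, genotyping-array design, F2 linkage mapping and diversity
analysis for inbred-line panels, built around the workflow that turns
whole-genome resequencing of a crop germplasm panel (the motivating case is
pepper, *Capsicum annuum*) into a fixed SNP array and its downstream
genetic analyses.

## What it does

**SNP discovery from pileups.** Per-sample text pileups are genotyped with
a sequencing-error correction: a base whose read fraction strictly exceeds
90% is called homozygous; otherwise the top two bases form a heterozygote.
Per-sample calls are merged onto the union of variant sites, and a site is
a SNP when two samples are homozygous for different alleles, each with
depth ≥ 3. SNPs with a neighbour within 50 bases are removed (both members
— the guard zone protects probe design), categorized by the phenotype
group(s) in which the calling rule holds (blocky / hot / both), and
annotated with containing genes.

**Array design.** For each SNP the 50 bp flanks are extracted, the
Infinium bead chemistry is classified (A/T and C/G pairs share a
fluorescence channel and need two bead types, Infinium I; all others are
Infinium II), and the manifest keeps one Infinium II marker per gene with
design score ≥ 0.8 and the minor allele carried by ≥ 2 of the 22 panel
samples.

**Array QC.** Call frequency, failed/functional and
monomorphic/polymorphic status per marker, cluster-score tiers, the MAF
spectrum in 0.05-wide bins, and counts of markers above MAF thresholds.

**F2 linkage mapping.** The recombination fraction r between two
codominant markers in an F2 is the MLE of the nine-class multinomial
likelihood (the double-heterozygote class mixes phases with
P = ((1−r)² + r²)/2), with LOD = log₁₀ L(r̂) − log₁₀ L(0.5). Markers are
grouped by single-linkage closure over (LOD, r) edges, ordered by
minimizing the sum of adjacent recombination fractions (exhaustive for ≤ 8
markers, greedy + 2-opt + relocation otherwise), and placed with the
Kosambi map function d = 25·ln((1+2r)/(1−2r)) cM. Adjacent markers with no
observed recombination collapse into bins; double-crossover scans flag
error-prone markers; heat-map matrices diagnose orders. Chromosomes broken
by a parental translocation are ordered piecewise and joined with
fixed-order distances, and maps are compared by R² over shared markers.

**Diversity analysis.** The maximal run of markers monomorphic within a
germplasm group around a focal gene (the selective-sweep signature around
the pungency gene *PUN1*), and the Evanno ΔK criterion
(ΔK = |L″(K)| / sd(lnP)) on replicate STRUCTURE-style likelihood tables.

**Synthetic data.** Every input is generated by the package itself:
references with non-overlapping genes, pileups with planted SNPs and
per-base error, F2 populations from Markov meioses along a known map (with
an optional reciprocal-translocation parent producing pseudolinkage), and
Balding–Nichols structured diversity panels with a planted fixed region.

## Worked example

```python
from peppermap import (SimConfig, make_f2_truth, simulate_f2, build_map,
                       kosambi_cM, estimate_rf)

truth = make_f2_truth(n_chrom=2, markers_per_chrom=40, chrom_cM=100.0, seed=1)
f2 = simulate_f2(truth, 90, SimConfig(seed=2, n_f2=90))

build = build_map(f2, lod_min=6.0)
gmap = build.gmap
print("linkage groups:", len(gmap.groups))
print("total map length: %.1f cM" % gmap.total_cM)
print("recombination bins:", gmap.n_bins)

pair = estimate_rf(f2.codes[0], f2.codes[1], *f2.markers[:2])
print(f"rf = {pair.r_hat:.3f}, LOD = {pair.lod:.1f}, "
      f"d = {kosambi_cM(pair.r_hat):.2f} cM")
```

prints

```
linkage groups: 2
total map length: 199.7 cM
recombination bins: 67
rf = 0.006, LOD = 38.0, d = 0.56 cM
```

Two simulated 100 cM chromosomes genotyped in 90 F2 individuals come back
as two linkage groups totalling 199.7 cM; the 80 markers collapse into 67
recombination bins (adjacent markers separated by no observed crossover
share a bin). The first two markers recombine in ~0.6% of meioses —
tightly linked, 0.56 Kosambi cM apart.

The same stages are scriptable from the shell:

```sh
peppermap --out-dir run1 --seed 3 simulate
peppermap --out-dir run1 discover      # pileups -> snps.vcf
peppermap --out-dir run1 design        # snps.vcf -> manifest.csv
peppermap --out-dir run1 map           # f2_abh.tsv -> map.tsv
```

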