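"""Genotyping-array marker selection.

From discovered SNPs: extract 50 bp flanking sequences, classify the
Infinium bead chemistry (same-fluorophore allele pairs A/T and C/G need two
bead types, Infinium I; all others one, Infinium II), compute panel minor
allele frequencies, and select at most one type-II, high-design-score,
sufficiently polymorphic marker per annotated gene.

The commercial assay-design score is proprietary, so the scoring function
is pluggable; the default stand-in scores by flank completeness, which is
deterministic and spans [0, 1].
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import pandas as pd

from .discovery import Snp


@dataclass(frozen=True)
class DesignParams:
    """Selection thresholds for the array manifest."""

    min_design_score: float = 0.8
    min_minor_count: int = 2  # minor allele present in >= this many samples
    panel_size: int = 22
    per_gene_limit: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.min_design_score <= 1:
            raise ValueError("min_design_score must be in [0, 1]")
        if self.min_minor_count < 1:
            raise ValueError("min_minor_count must be >= 1")


@dataclass(frozen=True)
class Flanks:
    flank5: str
    flank3: str
    truncated: bool


@dataclass
class MarkerCandidate:
    snp: Snp
    flank5: str
    flank3: str
    truncated: bool
    bead_type: str  # "I" | "II"
    design_score: float
    panel_maf: float  # allele-count form, in [0, 0.5]
    minor_carriers: int  # samples carrying the minor allele
    gene: str | None

    @property
    def assay_sequence(self) -> str:
        return f"{self.flank5}[{self.snp.ref}/{self.snp.alt}]{self.flank3}"


def extract_flanks(snp: Snp, ref, flank: int = 50) -> Flanks:
    """Upstream and downstream ``flank`` bases around a SNP (1-based).

    The 5' flank covers [pos-flank, pos-1] and the 3' flank [pos+1,
    pos+flank]; flanks truncated by a chromosome end are shorter and
    flagged.  A position outside the chromosome raises.
    """
    length = ref.chrom_lengths.get(snp.chrom)
    if length is None or not 1 <= snp.pos <= length:
        raise ValueError(f"SNP position {snp.chrom}:{snp.pos} outside reference")
    seq = ref.sequence[snp.chrom]
    lo = max(1, snp.pos - flank)
    hi = min(length, snp.pos + flank)
    flank5 = seq[lo - 1:snp.pos - 1]
    flank3 = seq[snp.pos:hi]
    return Flanks(flank5, flank3, len(flank5) < flank or len(flank3) < flank)


def bead_type(ref: str, alt: str) -> str:
    """Infinium bead-type class for an allele pair.

    A/T and C/G pairs share a fluorescence channel and need two bead types
    (Infinium I); every other pair is assayed with one (Infinium II).
    """
    if ref == alt:
        raise ValueError("allele pair must be two distinct bases")
    return "I" if {ref, alt} in ({"A", "T"}, {"C", "G"}) else "II"


def panel_maf(genotypes: Iterable[str], method: str = "allele") -> float:
    """Minor allele frequency of one SNP across panel genotypes.

    ``genotypes`` are two-letter strings ("AG") with "--" missing.  Method
    "allele": minor allele count / (2 x non-missing samples), in [0, 0.5].
    Method "carrier": fraction of non-missing samples carrying the minor
    allele (the literal 2-of-22 selection rule divides carriers by the
    panel size).
    """
    called = [g for g in genotypes if g != "--" and g is not None]
    if not called:
        raise ValueError("no non-missing genotypes")
    alleles = Counter("".join(called))
    if len(alleles) < 2:
        return 0.0
    minor = min(alleles, key=lambda a: (alleles[a], a))
    if method == "allele":
        return alleles[minor] / (2 * len(called))
    if method == "carrier":
        return sum(minor in g for g in called) / len(called)
    raise ValueError(f"unknown method {method!r}")


def minor_carrier_count(genotypes: Iterable[str]) -> int:
    """Number of samples carrying the minor allele (0 if monomorphic)."""
    called = [g for g in genotypes if g != "--" and g is not None]
    if not called:
        return 0
    alleles = Counter("".join(called))
    if len(alleles) < 2:
        return 0
    minor = min(alleles, key=lambda a: (alleles[a], a))
    return sum(minor in g for g in called)


def flank_completeness_score(cand_flanks: Flanks, flank: int = 50) -> float:
    """Default design-score stand-in: fraction of flank sequence present."""
    return (len(cand_flanks.flank5) + len(cand_flanks.flank3)) / (2 * flank)


def build_candidates(snps: Sequence[Snp], ref,
                     score_fn: Callable[[Flanks], float] | None = None,
                     flank: int = 50) -> list[MarkerCandidate]:
    """Assemble MarkerCandidates from annotated, genotyped SNPs."""
    if score_fn is None:
        score_fn = flank_completeness_score
    out = []
    for snp in snps:
        fl = extract_flanks(snp, ref, flank=flank)
        gts = list(snp.genotypes.values())
        out.append(MarkerCandidate(
            snp=snp, flank5=fl.flank5, flank3=fl.flank3,
            truncated=fl.truncated, bead_type=bead_type(snp.ref, snp.alt),
            design_score=float(score_fn(fl)),
            panel_maf=panel_maf(gts) if gts else 0.0,
            minor_carriers=minor_carrier_count(gts), gene=snp.gene))
    return out


def select_markers(candidates: Sequence[MarkerCandidate],
                   params: DesignParams) -> pd.DataFrame:
    """Select the array manifest: one Infinium II marker per gene.

    Filters: design score >= ``min_design_score``, bead type II, minor
    allele carried by >= ``min_minor_count`` panel samples, gene annotated.
    Among a gene's passing candidates the tie-break is highest design
    score, then highest panel MAF, then smallest genomic position.
    """
    passing = [c for c in candidates
               if c.design_score >= params.min_design_score
               and c.bead_type == "II"
               and c.minor_carriers >= params.min_minor_count
               and c.gene is not None]
    by_gene: dict[str, list[MarkerCandidate]] = {}
    for c in passing:
        by_gene.setdefault(c.gene, []).append(c)
    chosen = []
    for gene in sorted(by_gene):
        cands = sorted(by_gene[gene],
                       key=lambda c: (-c.design_score, -c.panel_maf,
                                      c.snp.chrom, c.snp.pos))
        chosen.extend(cands[:params.per_gene_limit])
    rows = [{
        "marker_id": f"{c.snp.chrom}_{c.snp.pos}",
        "chrom": c.snp.chrom, "pos": c.snp.pos,
        "ref": c.snp.ref, "alt": c.snp.alt,
        "flank5": c.flank5, "flank3": c.flank3,
        "assay_sequence": c.assay_sequence,
        "bead_type": c.bead_type,
        "design_score": round(c.design_score, 4),
        "panel_maf": round(c.panel_maf, 4),
        "minor_carriers": c.minor_carriers,
        "category": c.snp.category, "gene": c.gene,
    } for c in chosen]
    manifest = pd.DataFrame(rows, columns=[
        "marker_id", "chrom", "pos", "ref", "alt", "flank5", "flank3",
        "assay_sequence", "bead_type", "design_score", "panel_maf",
        "minor_carriers", "category", "gene"])
    return manifest.sort_values(["chrom", "pos"]).reset_index(drop=True)


def manifest_category_counts(manifest: pd.DataFrame) -> dict[str, int]:
    """Manifest size partitioned by phenotype category (sums to the total)."""
    counts = manifest["category"].value_counts(dropna=False).to_dict()
    return {str(k): int(v) for k, v in counts.items()}
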