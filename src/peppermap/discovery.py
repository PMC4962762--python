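"""SNP discovery from per-sample pileups.

Implements the resequencing SNP pipeline used to build the genotyping-array
candidate set: per-site diploid genotype calling with a >90% homozygosity
correction, merging of per-sample calls into a panel genotype table, the
two-differing-homozygotes calling rule with a minimum read depth, removal of
SNPs with close neighbours (probe-design guard zone), phenotype-group
categorization, and gene annotation.

All genomic coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")
MISSING = "-"


@dataclass(frozen=True)
class DiscoveryParams:
    """Thresholds of the SNP discovery pipeline.

    hom_fraction
        A base whose read fraction strictly exceeds this is called homozygous
        (the sequencing-error correction; default 0.90).
    min_depth
        Minimum read depth for a homozygote to support a SNP call (default 3).
    adjacency_window
        SNPs with another SNP within this many bases on the same chromosome
        are removed (default 50; distance is inclusive, both members go).
    min_support_genotypes
        Number of differing homozygous genotypes required to call a SNP
        (default 2).
    cross_group_both
        If True, a SNP polymorphic only *between* phenotype groups (fixed
        within each) is assigned to category "both" instead of being
        excluded. Default False: the strict "within-group" reading.
    """

    hom_fraction: float = 0.90
    min_depth: int = 3
    adjacency_window: int = 50
    min_support_genotypes: int = 2
    cross_group_both: bool = False

    def __post_init__(self) -> None:
        if not 0.5 < self.hom_fraction <= 1.0:
            raise ValueError("hom_fraction must be in (0.5, 1]")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.adjacency_window < 0:
            raise ValueError("adjacency_window must be >= 0")


@dataclass(frozen=True)
class GenotypeCall:
    """A diploid genotype call for one sample at one site."""

    sample: str
    alleles: tuple[str, str] | None  # sorted pair, or None when missing
    depth: int
    zygosity: str  # "hom" | "het" | "missing"

    @property
    def is_hom(self) -> bool:
        return self.zygosity == "hom"

    @property
    def gt(self) -> str:
        if self.alleles is None:
            return "--"
        return "".join(self.alleles)


def genotype_site(counts: Mapping[str, int], params: DiscoveryParams,
                  sample: str = "") -> GenotypeCall:
    """Call one sample's genotype from per-base read counts at a site.

    A base representing strictly more than ``hom_fraction`` of reads is
    called homozygous (this correction compensates for sequencing error in
    the consensus).  Otherwise the two most frequent bases are called
    heterozygous, provided no third base rises above a 1-read noise floor
    and there is no tie for the second allele.  Zero depth gives a missing
    call, as do degenerate inputs.
    """
    counts = {b: int(c) for b, c in counts.items() if c > 0}
    depth = sum(counts.values())
    if depth == 0:
        return GenotypeCall(sample, None, 0, "missing")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top_base, top_n = ranked[0]
    if top_n / depth > params.hom_fraction:
        return GenotypeCall(sample, (top_base, top_base), depth, "hom")
    if len(ranked) < 2:
        # single base but at/below the hom threshold cannot happen (fraction
        # would be 1); defensive
        return GenotypeCall(sample, (top_base, top_base), depth, "hom")
    second_base, second_n = ranked[1]
    # ambiguity: tie for the second allele
    if len(ranked) > 2 and ranked[2][1] == second_n:
        return GenotypeCall(sample, None, depth, "missing")
    # any third base above the noise floor of 1 read -> unreliable site
    if any(n > 1 for _, n in ranked[2:]):
        return GenotypeCall(sample, None, depth, "missing")
    alleles = tuple(sorted((top_base, second_base)))
    return GenotypeCall(sample, alleles, depth, "het")


@dataclass
class GenotypeTable:
    """Panel genotype table: sites x samples diploid calls with depths.

    ``sites`` is an ordered list of (chrom, pos, ref) keys; ``calls`` maps
    each site index to a dict sample -> GenotypeCall (missing samples get
    an explicit missing call).
    """

    sites: list[tuple[str, int, str]]
    samples: list[str]
    calls: list[dict[str, GenotypeCall]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("duplicate site keys in genotype table")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids in genotype table")

    def site_calls(self, i: int) -> dict[str, GenotypeCall]:
        return self.calls[i]

    def to_frame(self) -> pd.DataFrame:
        """Two-letter genotype codes ("AA", "AG", "--") as sites x samples."""
        data = {
            s: [self.calls[i][s].gt for i in range(len(self.sites))]
            for s in self.samples
        }
        idx = pd.MultiIndex.from_tuples(self.sites, names=["chrom", "pos", "ref"])
        return pd.DataFrame(data, index=idx)


def merge_tables(
    per_sample_calls: Sequence[tuple[str, Mapping[tuple[str, int, str], GenotypeCall]]],
    master_sites: Sequence[tuple[str, int, str]],
) -> GenotypeTable:
    """Merge per-sample call maps onto a master site list.

    Every master site gets one column per sample; samples without data at a
    site receive a missing call.  Duplicate sample ids or site keys raise.
    """
    samples = [s for s, _ in per_sample_calls]
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids passed to merge_tables")
    sites = list(master_sites)
    table = GenotypeTable(sites=sites, samples=samples)
    maps = dict(per_sample_calls)
    for site in sites:
        row = {}
        for s in samples:
            call = maps[s].get(site)
            if call is None:
                call = GenotypeCall(s, None, 0, "missing")
            row[s] = call
        table.calls.append(row)
    return table


@dataclass
class Snp:
    """A discovered biallelic SNP."""

    chrom: str
    pos: int
    ref: str
    alt: str
    category: str | None = None  # "blocky" | "hot" | "both"
    gene: str | None = None
    genotypes: dict[str, str] = field(default_factory=dict)  # sample -> "AG"/"--"

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("SNP ref and alt alleles must differ")


def _qualifying_homs(calls: Iterable[GenotypeCall],
                     params: DiscoveryParams) -> list[GenotypeCall]:
    return [c for c in calls
            if c.is_hom and c.depth >= params.min_depth]


def _snp_alleles(site_ref: str, homs: Sequence[GenotypeCall],
                 params: DiscoveryParams) -> tuple[str, str] | None:
    """Apply the calling rule to qualifying homozygotes at one site.

    Returns (ref, alt) if at least ``min_support_genotypes`` homozygous
    genotypes with differing alleles exist and the site is biallelic among
    qualifying homozygotes; None otherwise.
    """
    allele_counts: dict[str, int] = {}
    for c in homs:
        allele_counts[c.alleles[0]] = allele_counts.get(c.alleles[0], 0) + 1
    distinct = sorted(allele_counts, key=lambda a: (-allele_counts[a], a))
    if len(distinct) < 2 or len(homs) < params.min_support_genotypes:
        return None
    if len(distinct) > 2:
        return None  # multi-allelic among homozygotes: dropped
    a, b = distinct
    if site_ref in (a, b):
        ref = site_ref
        alt = b if a == site_ref else a
    else:
        ref, alt = a, b
    return ref, alt


def call_snps(table: GenotypeTable, params: DiscoveryParams) -> list[Snp]:
    """Call SNPs from a genotype table.

    A site is a SNP iff two samples are each homozygous with depth >=
    ``min_depth`` and carry different alleles; sites with more than two
    alleles among qualifying homozygotes are dropped (the array assays
    biallelic SNPs only).
    """
    snps: list[Snp] = []
    for i, (chrom, pos, site_ref) in enumerate(table.sites):
        calls = table.calls[i]
        homs = _qualifying_homs(calls.values(), params)
        alleles = _snp_alleles(site_ref, homs, params)
        if alleles is None:
            continue
        ref, alt = alleles
        genos = {s: calls[s].gt for s in table.samples}
        snps.append(Snp(chrom, pos, ref, alt, genotypes=genos))
    return snps


def filter_adjacent(snps: Sequence[Snp], params: DiscoveryParams) -> list[Snp]:
    """Remove SNPs with a neighbour within ``adjacency_window`` bases.

    Both members of a close pair are removed (the guard zone protects probe
    design, which fails for either member).  Input must be sorted by
    (chrom, pos); the operation is idempotent.
    """
    keys = [(s.chrom, s.pos) for s in snps]
    if keys != sorted(keys):
        raise ValueError("filter_adjacent requires SNPs sorted by (chrom, pos)")
    w = params.adjacency_window
    drop = [False] * len(snps)
    for i in range(len(snps) - 1):
        a, b = snps[i], snps[i + 1]
        if a.chrom == b.chrom and b.pos - a.pos <= w:
            drop[i] = drop[i + 1] = True
    return [s for s, d in zip(snps, drop) if not d]


def categorize_snp(
    snp: Snp,
    site_calls: Mapping[str, GenotypeCall],
    groups: Mapping[str, str],
    params: DiscoveryParams,
) -> str | None:
    """Assign a SNP to the blocky / hot / both phenotype sets.

    A SNP is "within" group G when the calling rule (two qualifying
    homozygotes with differing alleles) holds using only G's samples;
    "both" means it holds within each group separately.  A SNP polymorphic
    only *between* groups satisfies neither and is excluded (returns None)
    unless ``params.cross_group_both`` is set.
    """
    for s in site_calls:
        if s not in groups:
            raise ValueError(f"sample {s!r} has no group label")
    group_names = sorted(set(groups.values()))
    hits = []
    for g in group_names:
        calls = [c for s, c in site_calls.items() if groups[s] == g]
        homs = _qualifying_homs(calls, params)
        if _snp_alleles(snp.ref, homs, params) is not None:
            hits.append(g)
    if len(hits) == 0:
        if params.cross_group_both:
            homs = _qualifying_homs(site_calls.values(), params)
            if _snp_alleles(snp.ref, homs, params) is not None:
                return "both"
        return None
    if len(hits) == 1:
        return hits[0]
    return "both"


def categorize_snps(snps: Sequence[Snp], table: GenotypeTable,
                    groups: Mapping[str, str],
                    params: DiscoveryParams) -> list[Snp]:
    """Categorize every SNP; SNPs satisfying the rule in no group are dropped."""
    by_pos = {(site[0], site[1]): i for i, site in enumerate(table.sites)}
    out = []
    for snp in snps:
        i = by_pos.get((snp.chrom, snp.pos))
        if i is None:
            raise KeyError(f"SNP {snp.chrom}:{snp.pos} not in genotype table")
        cat = categorize_snp(snp, table.calls[i], groups, params)
        if cat is None:
            continue
        out.append(replace(snp, category=cat))
    return out


def annotate_genes(snps: Sequence[Snp], genes: pd.DataFrame) -> list[Snp]:
    """Annotate SNPs with the gene whose interval contains them.

    ``genes`` needs columns gene_id, chrom, start, end (1-based inclusive;
    boundary positions count as inside).  Overlapping gene intervals on a
    chromosome raise.
    """
    out = []
    by_chrom: dict[str, pd.DataFrame] = {}
    for chrom, sub in genes.groupby("chrom"):
        sub = sub.sort_values("start").reset_index(drop=True)
        if (sub["start"].values[1:] <= sub["end"].values[:-1]).any():
            raise ValueError(f"overlapping gene intervals on {chrom}")
        by_chrom[str(chrom)] = sub
    for snp in snps:
        gene = None
        sub = by_chrom.get(snp.chrom)
        if sub is not None:
            i = int(np.searchsorted(sub["start"].values, snp.pos, side="right")) - 1
            if i >= 0 and snp.pos <= int(sub["end"].iloc[i]):
                gene = str(sub["gene_id"].iloc[i])
        out.append(replace(snp, gene=gene))
    return out
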