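"""Vectorized genotype calling from pileup files.

The scalar rule lives in :func:`peppermap.discovery.genotype_site`; this
module applies the same rule to whole pileup files at once (base counts via
vectorized string ops) and assembles the panel genotype table the SNP caller
consumes: per-sample variant sites are merged onto the union 'master' site
list, mirroring a merged-pileup + per-sample-pileup workflow.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .discovery import (BASES, DiscoveryParams, GenotypeCall, GenotypeTable,
                        merge_tables)
from .io import read_pileup

# zygosity codes used internally by the vectorized classifier
_MISSING, _HOM, _HET = 0, 1, 2


def base_counts(pileup: pd.DataFrame) -> np.ndarray:
    """Per-site counts of A, C, G, T from the pileup bases column."""
    bases = pileup["bases"].astype(str).str.upper()
    return np.column_stack([bases.str.count(b).to_numpy() for b in BASES])


def classify_sites(counts: np.ndarray, params: DiscoveryParams
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized genotype calls from an (n_sites x 4) base-count array.

    Returns (zygosity, allele1, allele2, depth); alleles are indices into
    ``BASES`` (-1 when missing).  Semantics match ``genotype_site``: a base
    strictly above the homozygosity fraction is a homozygote; otherwise the
    top two bases are a heterozygote unless a third base exceeds the 1-read
    noise floor or ties the second.
    """
    counts = np.asarray(counts, dtype=np.int64)
    depth = counts.sum(axis=1)
    # stable argsort on descending counts: ties resolved alphabetically,
    # matching the scalar rule
    order = np.argsort(-counts, axis=1, kind="stable")
    ranked = np.take_along_axis(counts, order, axis=1)
    top, second, third = ranked[:, 0], ranked[:, 1], ranked[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(depth > 0, top / np.maximum(depth, 1), 0.0)
    zyg = np.full(len(depth), _MISSING, dtype=np.int8)
    a1 = np.full(len(depth), -1, dtype=np.int8)
    a2 = np.full(len(depth), -1, dtype=np.int8)

    hom = (depth > 0) & (frac > params.hom_fraction)
    zyg[hom] = _HOM
    a1[hom] = order[hom, 0]
    a2[hom] = order[hom, 0]

    het = (depth > 0) & ~hom & (second > 0) \
        & ~((third > 0) & (third == second)) & (third <= 1)
    zyg[het] = _HET
    lo = np.minimum(order[:, 0], order[:, 1])
    hi = np.maximum(order[:, 0], order[:, 1])
    a1[het] = lo[het]
    a2[het] = hi[het]
    return zyg, a1, a2, depth


class _ParsedPileup:
    """One sample's classified pileup held as arrays until needed."""

    def __init__(self, path: str | Path, sample: str,
                 params: DiscoveryParams) -> None:
        df = read_pileup(path)
        self.sample = sample
        counts = base_counts(df)
        self.zyg, self.a1, self.a2, self.depth = classify_sites(counts, params)
        refs = df["ref"].str.upper()
        ref_idx = refs.map({b: i for i, b in enumerate(BASES)}
                           ).fillna(-2).to_numpy()
        self.sites = list(zip(df["chrom"].astype(str),
                              df["pos"].astype(int), refs))
        self.row_of = {k: i for i, k in enumerate(self.sites)}
        var = (self.zyg == _HET) | ((self.zyg == _HOM) & (self.a1 != ref_idx))
        self.variants = {self.sites[i] for i in np.flatnonzero(var)}

    def call_at(self, site: tuple) -> GenotypeCall | None:
        i = self.row_of.get(site)
        if i is None:
            return None
        if self.zyg[i] == _MISSING:
            return GenotypeCall(self.sample, None, int(self.depth[i]), "missing")
        alleles = (BASES[self.a1[i]], BASES[self.a2[i]])
        return GenotypeCall(self.sample, alleles, int(self.depth[i]),
                            "hom" if self.zyg[i] == _HOM else "het")


def calls_from_pileup(path: str | Path, sample: str, params: DiscoveryParams
                      ) -> tuple[dict, set]:
    """Parse one sample's pileup into genotype calls.

    Returns (site -> GenotypeCall map, set of variant sites), where a
    variant site is any site whose call differs from homozygous-reference.
    Site keys are (chrom, pos, ref).
    """
    parsed = _ParsedPileup(path, sample, params)
    return {k: parsed.call_at(k) for k in parsed.sites}, parsed.variants


def build_genotype_table(pileups: Mapping[str, str | Path],
                         params: DiscoveryParams) -> GenotypeTable:
    """Build the panel genotype table from per-sample pileup files.

    The master site list is the union of each sample's variant sites
    (ordered by chromosome and position); every sample contributes its call
    at every master site, missing where it has no data.
    """
    parsed = [_ParsedPileup(pileups[s], s, params) for s in sorted(pileups)]
    master: set = set()
    for p in parsed:
        master |= p.variants
    master_sites = sorted(master)
    per_sample = []
    for p in parsed:
        calls = {}
        for site in master_sites:
            c = p.call_at(site)
            if c is not None:
                calls[site] = c
        per_sample.append((p.sample, calls))
    return merge_tables(per_sample, master_sites)
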