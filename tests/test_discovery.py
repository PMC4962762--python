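"""Unit and property tests for the pileup-based SNP discovery rules."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peppermap.discovery import (DiscoveryParams, GenotypeCall, GenotypeTable,
                                 Snp, annotate_genes, call_snps,
                                 categorize_snp, filter_adjacent,
                                 genotype_site, merge_tables)

P = DiscoveryParams()


def hom(sample, base, depth=10):
    return GenotypeCall(sample, (base, base), depth, "hom")


def het(sample, a, b, depth=10):
    return GenotypeCall(sample, tuple(sorted((a, b))), depth, "het")


def missing(sample):
    return GenotypeCall(sample, None, 0, "missing")


class TestGenotypeSite:
    @pytest.mark.parametrize("counts, zyg, alleles", [
        ({"A": 19, "C": 1}, "hom", ("A", "A")),       # 0.95 > 0.90
        ({"A": 9, "G": 1}, "het", ("A", "G")),        # 0.90 is NOT > 0.90
        ({}, "missing", None),
        ({"A": 10}, "hom", ("A", "A")),
        ({"A": 5, "G": 5}, "het", ("A", "G")),
        ({"A": 5, "G": 4, "T": 4}, "missing", None),  # tie for second allele
        ({"A": 6, "G": 4, "T": 2}, "missing", None),  # third base above floor
        ({"A": 6, "G": 4, "T": 1}, "het", ("A", "G")),
    ])
    def test_calling_rule(self, counts, zyg, alleles):
        call = genotype_site(counts, P)
        assert call.zygosity == zyg
        assert call.alleles == alleles

    @given(counts=st.dictionaries(st.sampled_from("ACGT"),
                                  st.integers(0, 60), max_size=4))
    @settings(max_examples=200, deadline=None)
    def test_raising_hom_fraction_never_creates_homozygotes(self, counts):
        loose = genotype_site(counts, DiscoveryParams(hom_fraction=0.8))
        strict = genotype_site(counts, DiscoveryParams(hom_fraction=0.95))
        if strict.zygosity == "hom":
            assert loose.zygosity == "hom"


class TestMergeTables:
    def test_union_semantics_fills_missing(self):
        s1 = {("c1", i, "A"): hom("s1", "G") for i in (10, 20, 30)}
        s2 = {("c1", i, "A"): hom("s2", "T") for i in (40, 50, 60)}
        sites = sorted(set(s1) | set(s2))
        t = merge_tables([("s1", s1), ("s2", s2)], sites)
        assert len(t.sites) == 6
        n_missing = sum(c.zygosity == "missing"
                        for row in t.calls for c in row.values())
        assert n_missing == 6

    def test_duplicate_sample_rejected(self):
        with pytest.raises(ValueError):
            merge_tables([("s1", {}), ("s1", {})], [])

    def test_empty_master(self):
        t = merge_tables([("s1", {})], [])
        assert t.sites == [] and t.calls == []


def make_table(site_calls):
    """site_calls: list of dict sample -> GenotypeCall at synthetic sites."""
    samples = sorted({s for row in site_calls for s in row})
    sites = [("c1", 100 * (i + 1), "A") for i in range(len(site_calls))]
    t = GenotypeTable(sites=sites, samples=samples)
    for row in site_calls:
        t.calls.append({s: row.get(s, missing(s)) for s in samples})
    return t


class TestCallSnps:
    def test_two_differing_homozygotes_make_a_snp(self):
        t = make_table([{"s1": hom("s1", "A", 3), "s2": hom("s2", "G", 3)}])
        snps = call_snps(t, P)
        assert len(snps) == 1
        assert {snps[0].ref, snps[0].alt} == {"A", "G"}

    def test_low_depth_support_rejected(self):
        t = make_table([{"s1": hom("s1", "A", 2), "s2": hom("s2", "G", 9)}])
        assert call_snps(t, P) == []

    def test_heterozygote_is_not_support(self):
        t = make_table([{"s1": hom("s1", "A"), "s2": het("s2", "A", "G")}])
        assert call_snps(t, P) == []

    def test_multiallelic_dropped(self):
        t = make_table([{"s1": hom("s1", "A"), "s2": hom("s2", "G"),
                         "s3": hom("s3", "T")}])
        assert call_snps(t, P) == []

    def test_raising_min_depth_never_increases_snps(self):
        rng = np.random.default_rng(0)
        t = random_table(rng, 8, 6)
        n = [len(call_snps(t, DiscoveryParams(min_depth=d)))
             for d in (1, 3, 5, 9)]
        assert n == sorted(n, reverse=True)


def random_table(rng, n_sites, n_samples):
    rows = []
    for _ in range(n_sites):
        row = {}
        for j in range(n_samples):
            s = f"s{j}"
            kind = rng.integers(0, 4)
            depth = int(rng.integers(0, 12))
            if kind == 0 or depth == 0:
                row[s] = missing(s)
            elif kind == 1:
                row[s] = hom(s, "ACGT"[rng.integers(0, 4)], depth)
            else:
                a, b = rng.choice(4, size=2, replace=False)
                row[s] = het(s, "ACGT"[a], "ACGT"[b], depth)
        rows.append(row)
    return make_table(rows)


def oracle_is_snp(calls, params):
    """Exhaustive pair enumeration: the calling rule checked literally."""
    homs = [c for c in calls
            if c.zygosity == "hom" and c.depth >= params.min_depth]
    has_pair = any(a.alleles != b.alleles
                   for a, b in itertools.combinations(homs, 2))
    return has_pair and len({c.alleles[0] for c in homs}) == 2


def test_call_snps_matches_pair_enumeration_oracle():
    rng = np.random.default_rng(42)
    for _ in range(200):
        t = random_table(rng, int(rng.integers(1, 6)), int(rng.integers(2, 5)))
        got = {(s.chrom, s.pos) for s in call_snps(t, P)}
        want = {site[:2] for site, row in zip(t.sites, t.calls)
                if oracle_is_snp(row.values(), P)}
        assert got == want


class TestFilterAdjacent:
    def snp(self, chrom, pos):
        return Snp(chrom, pos, "A", "G")

    def test_close_pair_both_removed(self):
        out = filter_adjacent([self.snp("c1", 100), self.snp("c1", 140)], P)
        assert out == []

    def test_distance_51_kept(self):
        snps = [self.snp("c1", 100), self.snp("c1", 151)]
        assert len(filter_adjacent(snps, P)) == 2

    def test_lone_snp_kept_and_chromosomes_independent(self):
        snps = [self.snp("c1", 100), self.snp("c2", 120)]
        assert len(filter_adjacent(snps, P)) == 2

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        snps = sorted((self.snp("c1", int(p))
                       for p in rng.choice(5000, 60, replace=False)),
                      key=lambda s: (s.chrom, s.pos))
        once = filter_adjacent(snps, P)
        assert filter_adjacent(once, P) == once

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            filter_adjacent([self.snp("c1", 200), self.snp("c1", 100)], P)


class TestCategorize:
    groups = {"b1": "blocky", "b2": "blocky", "h1": "hot", "h2": "hot"}

    def test_within_blocky_only(self):
        calls = {"b1": hom("b1", "A"), "b2": hom("b2", "G"),
                 "h1": hom("h1", "A"), "h2": hom("h2", "A")}
        snp = Snp("c1", 1, "A", "G")
        assert categorize_snp(snp, calls, self.groups, P) == "blocky"

    def test_both_groups(self):
        calls = {"b1": hom("b1", "A"), "b2": hom("b2", "G"),
                 "h1": hom("h1", "A"), "h2": hom("h2", "G")}
        snp = Snp("c1", 1, "A", "G")
        assert categorize_snp(snp, calls, self.groups, P) == "both"

    def test_between_group_only_excluded_by_default(self):
        calls = {"b1": hom("b1", "A"), "b2": hom("b2", "A"),
                 "h1": hom("h1", "G"), "h2": hom("h2", "G")}
        snp = Snp("c1", 1, "A", "G")
        assert categorize_snp(snp, calls, self.groups, P) is None
        relaxed = DiscoveryParams(cross_group_both=True)
        assert categorize_snp(snp, calls, self.groups, relaxed) == "both"

    def test_unlabeled_sample_rejected(self):
        calls = {"x9": hom("x9", "A")}
        with pytest.raises(ValueError):
            categorize_snp(Snp("c1", 1, "A", "G"), calls, self.groups, P)


class TestAnnotateGenes:
    genes = pd.DataFrame({"gene_id": ["g1"], "chrom": ["c1"],
                          "start": [100], "end": [200]})

    @pytest.mark.parametrize("pos, gene", [
        (100, "g1"), (200, "g1"), (150, "g1"), (99, None), (201, None)])
    def test_inclusive_boundaries(self, pos, gene):
        out = annotate_genes([Snp("c1", pos, "A", "G")], self.genes)
        assert out[0].gene == gene

    def test_overlapping_genes_rejected(self):
        bad = pd.DataFrame({"gene_id": ["g1", "g2"], "chrom": ["c1", "c1"],
                            "start": [100, 150], "end": [200, 260]})
        with pytest.raises(ValueError):
            annotate_genes([Snp("c1", 1, "A", "G")], bad)
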