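"""Synthetic data generation for every pipeline stage.

Three generators mirror the three data sources of a resequencing-to-array
study: (1) per-sample pileups over a reference with planted SNPs and
sequencing error, (2) an F2 mapping population produced by Markov meioses
along a known genetic map (optionally with a reciprocal-translocation
parent, which makes donor-tail markers co-segregate with the recipient
chromosome), and (3) a structured diversity panel with Balding-Nichols
group frequencies and an optional planted monomorphic region in one group.

All randomness flows through a single numpy Generator seeded from
``SimConfig.seed``; identical configurations give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .discovery import BASES
from .io import write_pileup
from .mapping import F2Matrix, inverse_kosambi

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study-scale simulation parameters.

    Defaults follow the scale of the emulated study: a 22-line resequencing
    panel (two phenotype groups of 11), ~20x read depth with 1% per-base
    error, 90 F2 individuals, and sub-1% missing array calls.  ``fst``
    controls between-group divergence of the diversity panel.
    """

    seed: int = 0
    depth_mean: float = 20.0
    error_rate: float = 0.01
    n_samples_per_group: int = 11
    n_f2: int = 90
    fst: float = 0.3
    missing_rate: float = 0.008

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if not 0 < self.fst < 1:
            raise ValueError("fst must be in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SimReference:
    """A reference genome stand-in: chromosome lengths, genes, sequence."""

    chrom_lengths: dict[str, int]
    genes: pd.DataFrame  # gene_id, chrom, start, end (1-based inclusive)
    sequence: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for _, row in self.genes.iterrows():
            L = self.chrom_lengths.get(row["chrom"])
            if L is None or not (1 <= row["start"] <= row["end"] <= L):
                raise ValueError(
                    f"gene {row['gene_id']} outside chromosome bounds")
        for chrom, sub in self.genes.groupby("chrom"):
            s = sub.sort_values("start")
            if (s["start"].values[1:] <= s["end"].values[:-1]).any():
                raise ValueError(f"overlapping genes on {chrom}")

    def base_at(self, chrom: str, pos: int) -> str:
        return self.sequence[chrom][pos - 1]


@dataclass
class PlantedTruth:
    """Ground truth for recovery tests.

    ``snps``: chrom, pos, ref, alt, true_category and one ``freq_<group>``
    column per panel group.  ``f2_map``: marker, chrom, bp, cM (true map).
    ``translocation``: (donor chrom, breakpoint bp, recipient chrom) or None.
    """

    snps: pd.DataFrame = field(default_factory=pd.DataFrame)
    f2_map: pd.DataFrame = field(default_factory=pd.DataFrame)
    translocation: tuple[str, int, str] | None = None

    def __post_init__(self) -> None:
        if len(self.snps):
            if self.snps.duplicated(["chrom", "pos"]).any():
                raise ValueError("duplicate planted SNP positions")
            for col in self.snps.columns:
                if col.startswith("freq_"):
                    f = self.snps[col]
                    if ((f < 0) | (f > 1)).any():
                        raise ValueError("allele frequencies must be in [0,1]")
        if len(self.f2_map):
            for _, sub in self.f2_map.groupby("chrom"):
                if (np.diff(sub["cM"].to_numpy()) < 0).any():
                    raise ValueError("cM positions must be non-decreasing")

    @property
    def groups(self) -> list[str]:
        return [c[5:] for c in self.snps.columns if c.startswith("freq_")]


# ---------------------------------------------------------------------------
# reference


def simulate_reference(n_chrom: int, chrom_len: int, n_genes: int, seed: int,
                       gene_len: int = 1000,
                       with_sequence: bool = True) -> SimReference:
    """Random reference: genes placed uniformly without overlap.

    Genes are spread over chromosomes as evenly as possible; an impossible
    packing (genes cannot fit) raises with the violated constraint named.
    """
    if n_genes * gene_len > n_chrom * chrom_len:
        raise ValueError(
            f"cannot pack {n_genes} genes of {gene_len} bp into "
            f"{n_chrom} x {chrom_len} bp: total gene length exceeds genome")
    rng = np.random.default_rng(seed)
    chroms = [f"Chr{i + 1:02d}" for i in range(n_chrom)]
    per_chrom = [n_genes // n_chrom + (1 if i < n_genes % n_chrom else 0)
                 for i in range(n_chrom)]
    rows = []
    gid = 0
    for chrom, g in zip(chroms, per_chrom):
        if g * gene_len > chrom_len:
            raise ValueError(
                f"cannot pack {g} genes of {gene_len} bp into {chrom} "
                f"({chrom_len} bp)")
        free = chrom_len - g * gene_len
        gaps = rng.multinomial(free, np.full(g + 1, 1.0 / (g + 1)))
        start = 0
        for k in range(g):
            start += gaps[k]
            rows.append({"gene_id": f"gene{gid + 1:05d}", "chrom": chrom,
                         "start": start + 1, "end": start + gene_len})
            start += gene_len
            gid += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    sequence = None
    if with_sequence:
        sequence = {
            c: _BASE_BYTES[rng.integers(0, 4, chrom_len)].tobytes().decode()
            for c in chroms
        }
    return SimReference({c: chrom_len for c in chroms}, genes, sequence)


# ---------------------------------------------------------------------------
# planted SNPs and panel pileups


def plant_snps(ref: SimReference, n_snps: int, rng: np.random.Generator,
               groups: Sequence[str] = ("blocky", "hot"),
               min_gap: int = 101,
               category_weights: Sequence[float] = (0.25, 0.25, 0.5),
               freq_range: tuple[float, float] = (0.2, 0.8)) -> PlantedTruth:
    """Plant isolated biallelic SNPs with group-wise allele frequencies.

    SNPs are at least ``min_gap`` bases apart (so none is lost to the
    adjacency filter) and at least 50 bases from chromosome ends (full
    flanks).  Each SNP is private to one group or shared by both, per
    ``category_weights``; the alternate-allele frequency in a carrying
    group is uniform on ``freq_range`` and exactly 0 elsewhere.
    """
    chroms = sorted(ref.chrom_lengths)
    lengths = np.array([ref.chrom_lengths[c] for c in chroms], dtype=float)
    alloc = np.floor(n_snps * lengths / lengths.sum()).astype(int)
    while alloc.sum() < n_snps:
        alloc[int(np.argmin(alloc / np.maximum(lengths, 1)))] += 1
    rows = []
    cats = ([groups[0]], [groups[1]], list(groups))
    for chrom, k in zip(chroms, alloc):
        if k == 0:
            continue
        L = ref.chrom_lengths[chrom]
        span = L - 100 - (k - 1) * (min_gap - 1)
        if span < k:
            raise ValueError(f"cannot place {k} SNPs {min_gap} bp apart on "
                             f"{chrom} ({L} bp)")
        x = np.sort(rng.choice(span, size=k, replace=False))
        pos = x + 51 + np.arange(k) * (min_gap - 1)
        for p in pos:
            p = int(p)
            refb = ref.base_at(chrom, p) if ref.sequence else "A"
            alt = BASES[(BASES.index(refb) + 1 + rng.integers(0, 3)) % 4]
            ci = rng.choice(len(cats), p=np.asarray(category_weights))
            carriers = cats[ci]
            row = {"chrom": chrom, "pos": p, "ref": refb, "alt": alt,
                   "true_category": "both" if len(carriers) > 1 else carriers[0]}
            for g in groups:
                row[f"freq_{g}"] = (float(rng.uniform(*freq_range))
                                    if g in carriers else 0.0)
            rows.append(row)
    snps = pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return PlantedTruth(snps=snps)


def _emitted_positions(length: int, snp_pos: np.ndarray,
                       site_window: int | None) -> np.ndarray:
    if site_window is None:
        return np.arange(1, length + 1)
    keep = np.zeros(length + 1, dtype=bool)
    for p in snp_pos:
        lo = max(1, p - site_window)
        hi = min(length, p + site_window)
        keep[lo:hi + 1] = True
    return np.flatnonzero(keep)


def simulate_panel_pileups(ref: SimReference, truth: PlantedTruth,
                           cfg: SimConfig, out_dir: str | Path,
                           site_window: int | None = None
                           ) -> tuple[dict[str, Path], pd.DataFrame]:
    """Write one pileup file per panel sample; return paths + true genotypes.

    Every sample's true genotype at a planted SNP is drawn from its group's
    allele frequency under Hardy-Weinberg.  Read depth per emitted site is
    Poisson(``depth_mean``); each read carries one of the sample's alleles
    and is corrupted to a uniformly random other base with probability
    ``error_rate``.  ``site_window`` restricts emitted sites to windows
    around planted SNPs (the pileup-with-position-list workflow); None
    emits every position.

    Returns ({sample: path}, truth genotype table) where the truth table is
    indexed by (chrom, pos, ref) with two-letter genotypes per sample.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    groups = truth.groups
    samples = [(g, f"{g}{i + 1:02d}") for g in groups
               for i in range(cfg.n_samples_per_group)]
    snps = truth.snps
    missing = [c for c in set(snps["chrom"]) if c not in ref.chrom_lengths]
    if missing:
        raise ValueError(f"planted SNPs on unknown chromosomes: {missing}")
    chroms = sorted(ref.chrom_lengths)

    # true genotypes: alt-allele dosage per sample, per SNP
    dosages = {}
    for g, s in samples:
        freqs = snps[f"freq_{g}"].to_numpy()
        dosages[s] = rng.binomial(2, freqs)

    truth_rows = {}
    for k, (_, row) in enumerate(snps.iterrows()):
        key = (row["chrom"], int(row["pos"]), row["ref"])
        gts = {}
        for _, s in samples:
            d = dosages[s][k]
            al = sorted([row["ref"]] * (2 - d) + [row["alt"]] * d)
            gts[s] = "".join(al)
        truth_rows[key] = gts
    truth_table = pd.DataFrame.from_dict(truth_rows, orient="index")
    truth_table.index = pd.MultiIndex.from_tuples(
        truth_table.index, names=["chrom", "pos", "ref"])

    base_index = {b: i for i, b in enumerate(BASES)}
    paths: dict[str, Path] = {}
    for g, s in sorted(samples, key=lambda t: t[1]):
        frames = []
        for chrom in chroms:
            L = ref.chrom_lengths[chrom]
            on_chrom = snps[snps["chrom"] == chrom]
            pos = _emitted_positions(L, on_chrom["pos"].to_numpy(), site_window)
            n = len(pos)
            if ref.sequence:
                seq = np.frombuffer(ref.sequence[chrom].encode(), np.uint8)
                ref_codes = np.searchsorted(_BASE_BYTES, seq[pos - 1])
            else:
                ref_codes = np.zeros(n, dtype=np.int64)
            a1 = ref_codes.copy()
            a2 = ref_codes.copy()
            if len(on_chrom):
                loc = np.searchsorted(pos, on_chrom["pos"].to_numpy())
                dose = dosages[s][on_chrom.index.to_numpy()]
                alt_codes = np.array([base_index[a] for a in on_chrom["alt"]])
                a1[loc] = np.where(dose >= 1, alt_codes, a1[loc])
                a2[loc] = np.where(dose == 2, alt_codes, ref_codes[loc])
            depth = rng.poisson(cfg.depth_mean, n)
            total = int(depth.sum())
            read_site = np.repeat(np.arange(n), depth)
            pick = rng.random(total) < 0.5
            alleles = np.where(pick, a1[read_site], a2[read_site])
            if cfg.error_rate > 0:
                err = rng.random(total) < cfg.error_rate
                shift = 1 + rng.integers(0, 3, int(err.sum()))
                alleles[err] = (alleles[err] + shift) % 4
            chars = _BASE_BYTES[alleles]
            offsets = np.concatenate([[0], np.cumsum(depth)])
            buf = chars.tobytes()
            strings = [buf[offsets[i]:offsets[i + 1]].decode()
                       for i in range(n)]
            frames.append(pd.DataFrame({
                "chrom": chrom, "pos": pos,
                "ref": [BASES[c] for c in ref_codes],
                "depth": depth, "bases": strings, "qual": "*",
            }))
        df = pd.concat(frames, ignore_index=True)
        path = out_dir / f"{s}.pileup"
        write_pileup(df, path)
        paths[s] = path
    return paths, truth_table


def panel_group_labels(truth: PlantedTruth, cfg: SimConfig) -> dict[str, str]:
    """Sample -> phenotype-group labels matching simulate_panel_pileups."""
    return {f"{g}{i + 1:02d}": g for g in truth.groups
            for i in range(cfg.n_samples_per_group)}


# ---------------------------------------------------------------------------
# F2 population


def make_f2_truth(n_chrom: int = 12, markers_per_chrom: int = 460,
                  chrom_cM: float = 116.0, chrom_len_bp: int = 10_000_000,
                  translocation: tuple[str, int, str] | None = None,
                  seed: int = 0, uniform: bool = False) -> PlantedTruth:
    """A true genetic map for F2 simulation.

    Marker cM positions are drawn uniformly per chromosome (or evenly spaced
    when ``uniform``); bp positions scale linearly with cM.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_chrom):
        chrom = f"Chr{c + 1:02d}"
        if uniform:
            cm = np.linspace(0, chrom_cM, markers_per_chrom)
        else:
            cm = np.sort(rng.uniform(0, chrom_cM, markers_per_chrom))
        bp = np.maximum(1, (cm / chrom_cM * chrom_len_bp)).astype(int)
        for i, (d, p) in enumerate(zip(cm, bp)):
            rows.append({"marker": f"{chrom}_m{i + 1:04d}", "chrom": chrom,
                         "bp": int(p), "cM": float(d)})
    return PlantedTruth(f2_map=pd.DataFrame(rows),
                        translocation=translocation)


def _segregation_frames(truth: PlantedTruth,
                        junction_cM: float) -> list[pd.DataFrame]:
    """Group markers into meiotic segregation frames.

    Without a translocation each chromosome is one frame.  With one, the
    donor chromosome's tail (markers past the breakpoint) is re-hung on the
    recipient chromosome at ``junction_cM`` beyond its last marker: in a
    balanced-gamete translocation heterozygote those markers co-segregate
    with the recipient chromosome.
    """
    fmap = truth.f2_map.copy()
    fmap["seg_chrom"] = fmap["chrom"]
    fmap["seg_cM"] = fmap["cM"]
    if truth.translocation is not None:
        donor, break_bp, recipient = truth.translocation
        tail = (fmap["chrom"] == donor) & (fmap["bp"] > break_bp)
        if tail.any():
            rec_max = fmap.loc[fmap["seg_chrom"] == recipient, "seg_cM"].max()
            tail_min = fmap.loc[tail, "cM"].min()
            fmap.loc[tail, "seg_chrom"] = recipient
            fmap.loc[tail, "seg_cM"] = (rec_max + junction_cM
                                        + fmap.loc[tail, "cM"] - tail_min)
    return [sub.sort_values(["seg_cM", "marker"]).reset_index(drop=True)
            for _, sub in fmap.groupby("seg_chrom", sort=True)]


def simulate_f2(truth: PlantedTruth, n_f2: int, cfg: SimConfig,
                junction_cM: float = 5.0) -> F2Matrix:
    """Simulate an F2 population over the true map.

    Gametes follow a Markov crossover process (no interference): along each
    segregation frame the allele switches between adjacent markers with
    probability equal to the inverse-Kosambi of their true distance.
    Genotypes are coded A/H/B with missing codes at ``missing_rate``;
    fully homozygous parents and an all-H F1 ride along in ``parents``.
    """
    rng = np.random.default_rng(cfg.seed)
    frames = _segregation_frames(truth, junction_cM)
    marker_order = list(truth.f2_map["marker"])
    codes = np.empty((len(marker_order), n_f2), dtype=np.int8)
    row_of = {m: i for i, m in enumerate(marker_order)}
    for frame in frames:
        m = len(frame)
        d = np.diff(frame["seg_cM"].to_numpy())
        r = inverse_kosambi(d)
        if np.any(r >= 0.5):
            raise ValueError("derived recombination fraction >= 0.5")
        start = rng.random((2 * n_f2, 1)) < 0.5
        switches = rng.random((2 * n_f2, m - 1)) < r
        alleles = np.cumsum(
            np.hstack([start, switches]).astype(np.int8), axis=1) % 2
        geno = (alleles[:n_f2] + alleles[n_f2:]).astype(np.int8)
        for j, mk in enumerate(frame["marker"]):
            codes[row_of[mk]] = geno[:, j]
    if cfg.missing_rate > 0:
        mask = rng.random(codes.shape) < cfg.missing_rate
        codes[mask] = -1
    individuals = [f"F2_{i + 1:03d}" for i in range(n_f2)]
    parents = pd.DataFrame(
        [["A"] * len(marker_order), ["B"] * len(marker_order),
         ["H"] * len(marker_order)],
        index=["parent_A", "parent_B", "F1"], columns=marker_order)
    info = truth.f2_map.set_index("marker")[["chrom", "bp", "cM"]]
    return F2Matrix(marker_order, individuals, codes,
                    marker_info=info, parents=parents)


# ---------------------------------------------------------------------------
# diversity panel


def simulate_diversity_panel(
    k_groups: int, n_markers: int, cfg: SimConfig,
    planted_block: tuple[str, tuple[int, int]] | None = None,
    chrom: str = "Chr02", spacing_bp: int = 46_000, cm_per_mb: float = 1.6,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Structured diversity panel with optional planted monomorphic block.

    Per-marker ancestral frequencies are Uniform(0.05, 0.95); each group's
    frequency is Balding-Nichols Beta(p(1-F)/F, (1-p)(1-F)/F) with
    divergence F = ``cfg.fst``.  Within ``planted_block`` (group name and
    inclusive marker-index range) the named group is fixed for one allele;
    the immediately flanking markers are forced polymorphic in that group so
    the planted block is exactly the maximal monomorphic run.

    Returns (genotypes markers x samples, marker table with chrom/bp/cM,
    sample -> group labels).  Genotypes are "AA"/"AB"/"BB"/"--".
    """
    if k_groups < 2:
        raise ValueError("need at least two groups")
    rng = np.random.default_rng(cfg.seed)
    groups = [f"G{i + 1}" for i in range(k_groups)]
    samples = [f"{g}_s{j + 1:02d}" for g in groups
               for j in range(cfg.n_samples_per_group)]
    labels = {s: s.split("_")[0] for s in samples}
    markers = [f"mk{i + 1:05d}" for i in range(n_markers)]
    p_anc = rng.uniform(0.05, 0.95, n_markers)
    F = cfg.fst
    shape = (1.0 - F) / F
    freq = {g: rng.beta(p_anc * shape, (1 - p_anc) * shape) for g in groups}
    if planted_block is not None:
        bg, (i0, i1) = planted_block
        if bg not in freq:
            raise ValueError(f"unknown group {bg!r} in planted_block")
        fixed = np.where(p_anc[i0:i1 + 1] >= 0.5, 1.0, 0.0)
        freq[bg][i0:i1 + 1] = fixed
    geno = {}
    for g in groups:
        for j in range(cfg.n_samples_per_group):
            s = f"{g}_s{j + 1:02d}"
            dose = rng.binomial(2, freq[g])
            gt = np.array(["AA", "AB", "BB"])[dose]
            if cfg.missing_rate > 0:
                gt = np.where(rng.random(n_markers) < cfg.missing_rate,
                              "--", gt)
            geno[s] = gt
    df = pd.DataFrame(geno, index=markers)
    if planted_block is not None:
        bg, (i0, i1) = planted_block
        guard = f"{bg}_s01"
        for flank in (i0 - 1, i1 + 1):
            if 0 <= flank < n_markers:
                df.iloc[flank, df.columns.get_loc(guard)] = "AB"
    bp = (np.arange(n_markers) + 1) * spacing_bp
    info = pd.DataFrame({"chrom": chrom, "bp": bp,
                         "cM": bp / 1e6 * cm_per_mb}, index=markers)
    return df, info, labels


# ---------------------------------------------------------------------------
# replicate log-likelihood tables (for the Evanno criterion)


def simulate_replicate_loglik(k_values: Sequence[int], true_k: int,
                              n_reps: int = 5, noise_sd: float = 1.0,
                              seed: int = 0, slope_before: float = 50.0,
                              slope_after: float = 2.0) -> pd.DataFrame:
    """Replicate lnP(K) tables with a planted elbow at ``true_k``.

    The mean lnP profile is piecewise linear with a slope break at the true
    K — the shape whose second difference (and hence the Evanno statistic)
    peaks at the planted value.  Returns a long table (replicate, K, lnP).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for k in k_values:
        base = slope_before * (min(k, true_k) - 1) \
            + slope_after * max(0, k - true_k)
        for rep in range(n_reps):
            rows.append({"replicate": rep + 1, "K": int(k),
                         "lnP": base + rng.normal(0.0, noise_sd)})
    return pd.DataFrame(rows)
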