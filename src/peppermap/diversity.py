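"""Diversity analyses on array genotypes.

Two analyses: (1) the maximal run of markers around a focal position at
which one germplasm group is monomorphic — the signature of a selective
sweep such as the fixed region around the pungency gene PUN1 in non-pungent
peppers — and (2) the Evanno ΔK criterion for choosing the number of
subpopulations K from replicate STRUCTURE-style log-likelihood tables.

Group assignments are inputs (phenotype labels or external clustering); a
light allele-sharing hierarchical clustering is provided for end-to-end
synthetic runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

MISSING_GT = "--"


@dataclass
class MonomorphicBlock:
    """A maximal run of within-group monomorphic markers."""

    chrom: str
    markers: list[str]
    group: str
    bp_span: int
    cM_span: float | None

    @property
    def n_markers(self) -> int:
        return len(self.markers)


def _is_monomorphic(calls: pd.Series) -> bool:
    """All called samples homozygous for one common allele.

    Heterozygous calls break the run (a swept region in inbreds is fixed);
    missing calls are ignored.  A marker with no called sample counts as
    monomorphic (no evidence against fixation).
    """
    called = [str(c) for c in calls if str(c) != MISSING_GT and not pd.isna(c)]
    if not called:
        return True
    first = called[0]
    return all(c == first and c[0] == c[1] for c in called)


def monomorphic_block(genotypes: pd.DataFrame, marker_info: pd.DataFrame,
                      labels: Mapping[str, str], focal, group: str,
                      chrom: str | None = None) -> MonomorphicBlock:
    """Maximal monomorphic run in ``group`` around a focal position.

    ``genotypes``: markers x samples two-letter calls; ``marker_info``:
    per-marker chrom, bp and optionally cM.  ``focal`` is a (chrom, bp)
    pair or a marker id.  Starting from the marker nearest the focal
    position, the run extends left and right while every called sample of
    the group is homozygous for one shared allele.  If the focal marker
    itself is polymorphic in the group the block is empty.  Returns the run
    with its physical (bp) and, when cM positions are present, genetic span.
    """
    if isinstance(focal, str):
        if focal not in marker_info.index:
            raise KeyError(f"unknown focal marker {focal!r}")
        chrom = str(marker_info.loc[focal, "chrom"])
        focal_bp = int(marker_info.loc[focal, "bp"])
    else:
        chrom, focal_bp = str(focal[0]), int(focal[1])
    info = marker_info[marker_info["chrom"] == chrom].sort_values("bp")
    if info.empty:
        raise ValueError(f"no markers on chromosome {chrom}")
    members = [s for s, g in labels.items()
               if g == group and s in genotypes.columns]
    if not members:
        raise ValueError(f"no samples labeled {group!r}")
    order = list(info.index)
    start = int(np.argmin(np.abs(info["bp"].to_numpy() - focal_bp)))
    mono = [_is_monomorphic(genotypes.loc[m, members]) for m in order]
    if not mono[start]:
        return MonomorphicBlock(chrom, [], group, 0, 0.0)
    lo = start
    while lo > 0 and mono[lo - 1]:
        lo -= 1
    hi = start
    while hi < len(order) - 1 and mono[hi + 1]:
        hi += 1
    run = order[lo:hi + 1]
    bp = info.loc[run, "bp"]
    bp_span = int(bp.max() - bp.min())
    cm_span = None
    if "cM" in info.columns:
        cm = info.loc[run, "cM"].astype(float)
        cm_span = float(cm.max() - cm.min())
    return MonomorphicBlock(chrom, run, group, bp_span, cm_span)


def block_report(block: MonomorphicBlock) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": block.chrom, "group": block.group,
        "n_markers": block.n_markers, "bp_span": block.bp_span,
        "cM_span": (round(block.cM_span, 1)
                    if block.cM_span is not None else np.nan),
        "first_marker": block.markers[0] if block.markers else "",
        "last_marker": block.markers[-1] if block.markers else "",
    }])


# ---------------------------------------------------------------------------
# Evanno ΔK


def evanno_delta_k(lnp: pd.DataFrame) -> pd.DataFrame:
    """Evanno ΔK table from replicate log-likelihoods.

    ``lnp`` is a long table with columns replicate, K, lnP over at least
    three consecutive K values with at least two replicates each.  Per K:
    L(K) = mean lnP, L'(K) = L(K) - L(K-1), |L''(K)| = |L'(K+1) - L'(K)|,
    ΔK = |L''(K)| / sd(lnP at K) (sample sd).  ΔK is defined only at
    interior K with sd > 0; zero-sd rows carry NaN and are flagged.
    ΔK is invariant to adding a constant to every lnP value.
    """
    need = {"replicate", "K", "lnP"}
    if not need <= set(lnp.columns):
        raise ValueError(f"lnP table needs columns {sorted(need)}")
    g = lnp.groupby("K")["lnP"]
    table = pd.DataFrame({"mean_lnP": g.mean(), "sd_lnP": g.std(ddof=1),
                          "n_reps": g.size()}).sort_index()
    ks = table.index.to_numpy()
    if len(ks) < 3 or (np.diff(ks) != 1).any():
        raise ValueError("need >= 3 consecutive K values")
    if (table["n_reps"] < 2).any():
        raise ValueError("need >= 2 replicates per K")
    L = table["mean_lnP"].to_numpy()
    L1 = np.full(len(ks), np.nan)
    L1[1:] = np.diff(L)
    L2 = np.full(len(ks), np.nan)
    L2[1:-1] = np.abs(L1[2:] - L1[1:-1])
    sd = table["sd_lnP"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        dk = np.where(sd > 0, L2 / sd, np.nan)
    table["L1"] = L1
    table["L2_abs"] = L2
    table["delta_K"] = dk
    table["sd_zero"] = (sd == 0) & ~np.isnan(L2)
    return table.reset_index()


def best_k(table: pd.DataFrame) -> int:
    """The K maximizing ΔK (ties: the smallest such K)."""
    ok = table.dropna(subset=["delta_K"])
    if ok.empty:
        raise ValueError("ΔK undefined everywhere")
    return int(ok.loc[ok["delta_K"].idxmax(), "K"])


# ---------------------------------------------------------------------------
# plumbing: allele-sharing clustering for end-to-end synthetic runs


def cluster_samples(genotypes: pd.DataFrame, k: int) -> dict[str, str]:
    """Group samples by average-linkage clustering on allele-sharing distance.

    Distance between two samples is 1 - (shared alleles / 2) averaged over
    markers called in both.  Returns sample -> "C1".."Ck" labels.  This is
    plumbing for synthetic end-to-end runs, not an admixture model.
    """
    dose = genotypes.apply(
        lambda col: col.map({"AA": 0, "AB": 1, "BA": 1, "BB": 2}))
    X = dose.to_numpy(dtype=float).T  # samples x markers
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(X - X[i])
        ok = ~np.isnan(diff)
        D[i] = np.where(ok.sum(axis=1) > 0,
                        np.nansum(diff, axis=1) / (2 * np.maximum(ok.sum(axis=1), 1)),
                        1.0)
        D[i, i] = 0.0
    D = (D + D.T) / 2
    Z = hierarchy.average(squareform(D, checks=False))
    assign = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return {s: f"C{c}" for s, c in zip(genotypes.columns, assign)}
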