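"""F2 genetic-map construction.

Pairwise recombination-fraction estimation for codominant F2 genotypes
(multinomial MLE over the nine two-locus classes), LOD scores, Kosambi map
distances, single-linkage grouping, marker ordering by minimum SARF (sum of
adjacent recombination fractions), recombination-bin collapsing,
double-crossover diagnostics, rf heat-map matrices, fixed-order assembly of
independently ordered segments (the translocation workflow), and map-to-map
correlation.

Genotype codes are integers: 0 = A (parent-1 homozygote), 1 = H
(heterozygote), 2 = B (parent-2 homozygote), -1 = missing.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats

CODE_OF = {"A": 0, "H": 1, "B": 2, "-": -1}
LETTER_OF = {v: k for k, v in CODE_OF.items()}

_LN10 = math.log(10.0)
_R_EPS = 1e-9


# ---------------------------------------------------------------------------
# containers


@dataclass
class F2Matrix:
    """Markers x individuals codominant F2 genotypes ('ABH' coding)."""

    markers: list[str]
    individuals: list[str]
    codes: np.ndarray  # int8, shape (n_markers, n_individuals)
    marker_info: pd.DataFrame | None = None  # index marker; chrom, bp, cM
    parents: pd.DataFrame | None = None  # parent/F1 rows, letter coded

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.markers), len(self.individuals)):
            raise ValueError("codes shape does not match marker/individual ids")
        bad = ~np.isin(self.codes, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("F2 codes must be in {A,H,B,missing}")

    def to_frame(self) -> pd.DataFrame:
        letters = np.vectorize(LETTER_OF.get)(self.codes)
        return pd.DataFrame(letters, index=self.markers, columns=self.individuals)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "F2Matrix":
        codes = df.map(lambda x: CODE_OF.get(str(x), -1)).to_numpy(dtype=np.int8)
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   codes, **kwargs)

    def write_tsv(self, path: str | Path, header: str | None = None) -> None:
        from .io import write_matrix_tsv
        write_matrix_tsv(self.to_frame(), path, header=header)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "F2Matrix":
        from .io import read_matrix_tsv
        return cls.from_frame(read_matrix_tsv(path, dtype=str))


@dataclass(frozen=True)
class LinkagePair:
    marker_i: str
    marker_j: str
    r_hat: float
    lod: float
    n_informative: int


@dataclass
class GeneticMap:
    """Ordered linkage groups with cumulative Kosambi cM positions and bins."""

    groups: list[list[str]]  # ordered marker ids per linkage group
    positions: dict[str, float]  # cM within the group, 0 at the first marker
    bins: dict[str, int]  # globally unique recombination-bin id per marker

    @property
    def total_cM(self) -> float:
        return float(sum(self.positions[g[-1]] - self.positions[g[0]]
                         for g in self.groups if g))

    @property
    def n_bins(self) -> int:
        return len(set(self.bins.values()))

    def group_of(self) -> dict[str, int]:
        return {m: gi for gi, g in enumerate(self.groups) for m in g}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gi, g in enumerate(self.groups):
            for m in g:
                rows.append({"marker": m, "group": gi + 1,
                             "cM": round(self.positions[m], 1),
                             "bin": self.bins[m]})
        return pd.DataFrame(rows).set_index("marker")


# ---------------------------------------------------------------------------
# Kosambi map function


def kosambi_cM(r):
    """Kosambi map distance d = 25 * ln((1+2r)/(1-2r)) in centiMorgans."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must be in [0, 0.5)")
    d = 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    return float(d) if d.ndim == 0 else d

def inverse_kosambi(d_cM):
    """Inverse Kosambi: r = 0.5 * tanh(d/50) for d in centiMorgans."""
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# pairwise recombination fraction


def _class_counts(gi: np.ndarray, gj: np.ndarray) -> tuple[int, int, int, int, int]:
    """Sufficient statistics of the F2 two-locus likelihood.

    Returns (n_parental_corner, n_edge, n_recombinant_corner, n_center, N):
    corners are double homozygotes (0 or 2 recombinant gametes), edges are
    hom x het (1), the center is the double heterozygote (phase-ambiguous).
    """
    ok = (gi >= 0) & (gj >= 0)
    a, b = gi[ok], gj[ok]
    n0 = int(np.sum(((a == 0) & (b == 0)) | ((a == 2) & (b == 2))))
    n2 = int(np.sum(((a == 0) & (b == 2)) | ((a == 2) & (b == 0))))
    nc = int(np.sum((a == 1) & (b == 1)))
    n = int(ok.sum())
    n1 = n - n0 - n2 - nc
    return n0, n1, n2, nc, n


def _loglik(r: float, n0: int, n1: int, n2: int, nc: int) -> float:
    """Log-likelihood of the two-locus F2 multinomial at recombination r.

    Class probabilities: parental corners (1-r)^2/4 each, edges r(1-r)/2
    each, recombinant corners r^2/4 each, double het ((1-r)^2 + r^2)/2.
    """
    s = 1.0 - r
    ll = 0.0
    if n0:
        ll += n0 * (math.log(s * s / 4.0) if s > 0 else -math.inf)
    if n1:
        ll += n1 * (math.log(r * s / 2.0) if 0 < r < 1 else -math.inf)
    if n2:
        ll += n2 * (math.log(r * r / 4.0) if r > 0 else -math.inf)
    if nc:
        ll += nc * math.log((s * s + r * r) / 2.0)
    return ll


def estimate_rf(gi: np.ndarray, gj: np.ndarray,
                marker_i: str = "i", marker_j: str = "j") -> LinkagePair:
    """MLE of the recombination fraction between two codominant F2 markers.

    Maximizes the nine-class multinomial likelihood by bounded scalar search
    on [0, 0.5]; the double-heterozygote class mixes parental and recombinant
    phases with P = ((1-r)^2 + r^2)/2.  LOD is log10 L(r_hat) - log10 L(0.5).
    """
    gi = np.asarray(gi, dtype=np.int8)
    gj = np.asarray(gj, dtype=np.int8)
    n0, n1, n2, nc, n = _class_counts(gi, gj)
    if n == 0:
        raise ValueError("no individuals informative for both markers")
    res = optimize.minimize_scalar(
        lambda r: -_loglik(r, n0, n1, n2, nc),
        bounds=(_R_EPS, 0.5 - _R_EPS), method="bounded",
        options={"xatol": 1e-8})
    candidates = [float(res.x), 0.0, 0.5]
    r_hat = max(candidates, key=lambda r: _loglik(r, n0, n1, n2, nc))
    lod = (_loglik(r_hat, n0, n1, n2, nc)
           - _loglik(0.5, n0, n1, n2, nc)) / _LN10
    return LinkagePair(marker_i, marker_j, r_hat, max(lod, 0.0), n)


def pairwise_rf(codes: np.ndarray, max_iter: int = 200,
                tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs recombination fractions via vectorized EM.

    Computes the class counts for every marker pair with indicator-matrix
    products, then iterates the standard F2 EM (expected recombinant gametes
    over 2N meioses; the double-het class contributes 2r^2/((1-r)^2+r^2)).
    The EM fixed point is the same MLE found by ``estimate_rf``.

    Returns (R, LOD, N): symmetric (m x m) arrays of r_hat, LOD score and
    informative-individual counts.  Pairs with no shared individuals get
    r = nan, LOD = 0.
    """
    codes = np.asarray(codes, dtype=np.int8)
    m = codes.shape[0]
    x0 = (codes == 0).astype(np.float32)
    x1 = (codes == 1).astype(np.float32)
    x2 = (codes == 2).astype(np.float32)
    valid = (codes >= 0).astype(np.float32)

    n0 = x0 @ x0.T + x2 @ x2.T
    cross = x0 @ x2.T
    n2 = cross + cross.T
    nc = x1 @ x1.T
    nn = valid @ valid.T
    n1 = nn - n0 - n2 - nc

    iu = np.triu_indices(m, k=1)
    c0 = n0[iu].astype(np.float64)
    c1 = n1[iu].astype(np.float64)
    c2 = n2[iu].astype(np.float64)
    cc = nc[iu].astype(np.float64)
    ntot = nn[iu].astype(np.float64)

    informative = ntot > 0
    denom = np.where(informative, 2.0 * ntot, 1.0)
    r = np.full(c0.shape, 0.25)
    for _ in range(max_iter):
        s = 1.0 - r
        w = (2.0 * r * r) / (s * s + r * r)
        r_new = (c1 + 2.0 * c2 + cc * w) / denom
        np.clip(r_new, _R_EPS, 0.5, out=r_new)
        delta = np.max(np.abs(r_new - r)) if r.size else 0.0
        r = r_new
        if delta < tol:
            break
    r = np.where(informative, r, np.nan)

    def _ll_vec(rv: np.ndarray) -> np.ndarray:
        sv = 1.0 - rv
        rv_ = np.clip(rv, _R_EPS, 0.5)
        sv_ = np.clip(sv, _R_EPS, 1.0)
        out = c0 * np.log(sv_ * sv_ / 4.0)
        out += c1 * np.log(rv_ * sv_ / 2.0)
        out += c2 * np.log(rv_ * rv_ / 4.0)
        out += cc * np.log((sv_ * sv_ + rv_ * rv_) / 2.0)
        return out

    with np.errstate(invalid="ignore"):
        lod = (_ll_vec(np.where(informative, r, 0.5))
               - _ll_vec(np.full_like(r, 0.5))) / _LN10
    lod = np.where(informative, np.maximum(lod, 0.0), 0.0)

    R = np.full((m, m), np.nan)
    L = np.zeros((m, m))
    np.fill_diagonal(R, 0.0)
    R[iu] = r
    R.T[iu] = r
    L[iu] = lod
    L.T[iu] = lod
    return R, L, nn.astype(np.int64)


# ---------------------------------------------------------------------------
# grouping


def group_markers(R: np.ndarray, LOD: np.ndarray, marker_ids: Sequence[str],
                  lod_min: float = 3.0, r_max: float = 0.4,
                  criterion: str = "lod",
                  alpha: float = 0.05) -> list[list[str]]:
    """Partition markers into linkage groups by single-linkage closure.

    An edge joins two markers when LOD >= lod_min and r <= r_max (default),
    or, in "pvalue" mode, when the likelihood-ratio test of independence
    (chi-square with 1 df on 2 ln10 * LOD) gives p < alpha and r <= r_max.
    Groups are numbered by decreasing size, ties by lowest marker index, so
    output is deterministic.  Markers with no qualifying edge become
    singletons.
    """
    marker_ids = list(marker_ids)
    with np.errstate(invalid="ignore"):
        if criterion == "lod":
            adj = (LOD >= lod_min) & (R <= r_max)
        elif criterion == "pvalue":
            pvals = stats.chi2.sf(2.0 * _LN10 * LOD, df=1)
            adj = (pvals < alpha) & (R <= r_max)
        else:
            raise ValueError(f"unknown grouping criterion {criterion!r}")
    adj = np.asarray(adj) & ~np.eye(len(marker_ids), dtype=bool)
    n_comp, labels = sparse.csgraph.connected_components(
        sparse.csr_matrix(adj), directed=False)
    groups = [np.flatnonzero(labels == c) for c in range(n_comp)]
    groups.sort(key=lambda idx: (-len(idx), int(idx.min())))
    return [[marker_ids[i] for i in idx] for idx in groups]


# ---------------------------------------------------------------------------
# ordering


def sarf(order: Sequence[int], R: np.ndarray) -> float:
    """Sum of adjacent recombination fractions along an order."""
    o = np.asarray(order)
    vals = R[o[:-1], o[1:]]
    return float(np.nansum(vals))


def _greedy_path(R: np.ndarray) -> list[int]:
    n = R.shape[0]
    D = np.where(np.isnan(R), 0.5, R).copy()
    np.fill_diagonal(D, np.inf)
    i, j = np.unravel_index(np.argmin(D), D.shape)
    if i > j:
        i, j = j, i
    path = [int(i), int(j)]
    placed = np.zeros(n, dtype=bool)
    placed[[i, j]] = True
    while len(path) < n:
        head, tail = path[0], path[-1]
        dh = np.where(placed, np.inf, D[head])
        dt = np.where(placed, np.inf, D[tail])
        ch, ct = int(np.argmin(dh)), int(np.argmin(dt))
        if dh[ch] < dt[ct]:
            path.insert(0, ch)
            placed[ch] = True
        else:
            path.append(ct)
            placed[ct] = True
    return path


def _best_2opt(order: list[int], D: np.ndarray) -> tuple[float, int, int]:
    """Best segment-reversal move; returns (delta, i, j), delta < 0 improves."""
    n = len(order)
    o = np.asarray(order)
    best = (0.0, -1, -1)
    # interior reversals [i..j], 1 <= i <= j <= n-2
    for i in range(1, n - 1):
        j = np.arange(i, n - 1)
        delta = (D[o[i - 1], o[j]] - D[o[i - 1], o[i]]
                 + D[o[i], o[j + 1]] - D[o[j], o[j + 1]])
        k = int(np.argmin(delta))
        if delta[k] < best[0] - 1e-15:
            best = (float(delta[k]), i, int(j[k]))
    # prefix reversals [0..j], j <= n-2
    j = np.arange(0, n - 1)
    delta = D[o[0], o[j + 1]] - D[o[j], o[j + 1]]
    k = int(np.argmin(delta))
    if delta[k] < best[0] - 1e-15:
        best = (float(delta[k]), 0, int(j[k]))
    # suffix reversals [i..n-1], i >= 1
    i = np.arange(1, n)
    delta = D[o[i - 1], o[n - 1]] - D[o[i - 1], o[i]]
    k = int(np.argmin(delta))
    if delta[k] < best[0] - 1e-15:
        best = (float(delta[k]), int(i[k]), n - 1)
    return best


def _best_relocation(order: list[int], D: np.ndarray) -> tuple[float, int, int]:
    """Best single-marker move; returns (delta, from_pos, insert_gap)."""
    n = len(order)
    o = np.asarray(order)
    best = (0.0, -1, -1)
    edge = D[o[:-1], o[1:]]
    for k in range(n):
        m = o[k]
        gain = 0.0
        if 0 < k < n - 1:
            gain = edge[k - 1] + edge[k] - D[o[k - 1], o[k + 1]]
        elif k == 0:
            gain = edge[0]
        else:
            gain = edge[n - 2]
        rest = np.delete(o, k)
        # insertion gaps: 0 = front, g = between rest[g-1], rest[g], len = back
        cost = np.empty(n)
        cost[0] = D[m, rest[0]]
        cost[-1] = D[rest[-1], m]
        if n > 2:
            g = np.arange(1, n - 1)
            cost[1:-1] = (D[rest[g - 1], m] + D[m, rest[g]]
                          - D[rest[g - 1], rest[g]])
        delta = cost - gain  # reinsertion at the original gap gives delta 0
        t = int(np.argmin(delta))
        if delta[t] < best[0] - 1e-15:
            best = (float(delta[t]), k, t)
    return best


def _apply_relocation(order: list[int], k: int, gap: int) -> list[int]:
    m = order[k]
    rest = order[:k] + order[k + 1:]
    return rest[:gap] + [m] + rest[gap:]


def order_markers(marker_ids: Sequence[str], R: np.ndarray,
                  exhaustive_limit: int = 8,
                  anchor: str | None = None) -> list[str]:
    """Order a linkage group's markers by minimum SARF.

    Groups of at most ``exhaustive_limit`` markers are solved exactly by
    enumeration; larger groups use greedy nearest-neighbour construction
    from the tightest pair followed by 2-opt (segment reversal) and ripple
    (single-marker relocation) improvement until neither move helps.
    Orientation is canonicalized so the first marker id sorts before the
    last, unless ``anchor`` names a marker that should sit in the first half.
    """
    marker_ids = list(marker_ids)
    n = len(marker_ids)
    if n <= 2:
        return sorted(marker_ids) if anchor is None else marker_ids
    D = np.where(np.isnan(R), 0.5, np.asarray(R, dtype=float))
    if n <= exhaustive_limit:
        best_order, best_val = None, math.inf
        for perm in itertools.permutations(range(n)):
            if perm[0] > perm[-1]:
                continue
            val = sarf(perm, D)
            if val < best_val - 1e-15:
                best_val, best_order = val, list(perm)
        order = best_order
    else:
        order = _greedy_path(D)
        improved = True
        while improved:
            improved = False
            delta, i, j = _best_2opt(order, D)
            if delta < -1e-15:
                order = order[:i] + order[i:j + 1][::-1] + order[j + 1:]
                improved = True
                continue
            delta, k, gap = _best_relocation(order, D)
            if delta < -1e-15:
                order = _apply_relocation(order, k, gap)
                improved = True
    ids = [marker_ids[i] for i in order]
    if anchor is not None and anchor in ids:
        if ids.index(anchor) >= n / 2:
            ids = ids[::-1]
    elif ids[0] > ids[-1]:
        ids = ids[::-1]
    return ids


# ---------------------------------------------------------------------------
# bins, positions, diagnostics


def map_positions(ordered_ids: Sequence[str], R: np.ndarray,
                  index_of: Mapping[str, int]) -> dict[str, float]:
    """Cumulative Kosambi cM positions along a fixed marker order."""
    pos = {ordered_ids[0]: 0.0}
    total = 0.0
    for a, b in zip(ordered_ids[:-1], ordered_ids[1:]):
        r = R[index_of[a], index_of[b]]
        r = 0.5 - _R_EPS if (np.isnan(r) or r >= 0.5) else max(float(r), 0.0)
        total += kosambi_cM(r)
        pos[b] = total
    return pos


def collapse_bins(codes: np.ndarray, min_shared: int = 1,
                  mode: str = "zero_recombination") -> np.ndarray:
    """Assign recombination-bin ids to markers in their given order.

    Adjacent markers share a bin when no recombination event is observed
    between them: their genotypes agree for every individual called at both
    (mode "zero_recombination"), with at least ``min_shared`` such
    individuals.  Mode "identical" additionally requires the same missing
    pattern.  Bin ids are 0-based and increase along the order.
    """
    codes = np.asarray(codes)
    m = codes.shape[0]
    bins = np.zeros(m, dtype=int)
    for i in range(1, m):
        a, b = codes[i - 1], codes[i]
        if mode == "identical":
            same = bool(np.array_equal(a, b))
        else:
            shared = (a >= 0) & (b >= 0)
            same = (int(shared.sum()) >= min_shared
                    and bool(np.all(a[shared] == b[shared])))
        bins[i] = bins[i - 1] if same else bins[i - 1] + 1
    return bins


def double_crossover_scan(codes: np.ndarray, flank_reach: int = 5,
                          sd_mult: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Count apparent double crossovers per marker and flag outliers.

    For each individual and interior marker, a DCO is a genotype differing
    from equal nearest non-missing flanking genotypes, with both flanks
    within ``flank_reach`` markers.  Markers whose DCO count exceeds the
    group mean by more than ``sd_mult`` standard deviations are flagged —
    these are the 'problematic markers' that inflate map length.
    """
    codes = np.asarray(codes)
    m, n = codes.shape
    counts = np.zeros(m, dtype=int)
    for ind in range(n):
        col = codes[:, ind]
        idx = np.flatnonzero(col >= 0)
        if idx.size < 3:
            continue
        left, mid, right = idx[:-2], idx[1:-1], idx[2:]
        hit = ((col[left] == col[right]) & (col[mid] != col[left])
               & (mid - left <= flank_reach) & (right - mid <= flank_reach))
        np.add.at(counts, mid[hit], 1)
    mu, sd = counts.mean(), counts.std()
    flags = counts > mu + sd_mult * sd if sd > 0 else np.zeros(m, dtype=bool)
    return counts, flags


def rf_heatmap(ordered_ids: Sequence[str], R: np.ndarray,
               index_of: Mapping[str, int]) -> tuple[pd.DataFrame, float]:
    """Pairwise-rf matrix in map order plus an order-quality statistic.

    The statistic is the mean over rows of the Spearman correlation between
    |i - j| and r_hat: close to 1 when genetic distance grows with distance
    in the order (a correct order), lower when markers are misplaced.
    """
    idx = [index_of[m] for m in ordered_ids]
    sub = np.asarray(R)[np.ix_(idx, idx)]
    n = len(idx)
    rhos = []
    offsets = np.arange(n)
    for i in range(n):
        d = np.abs(offsets - i)
        mask = (offsets != i) & ~np.isnan(sub[i])
        if mask.sum() >= 3 and np.nanstd(sub[i][mask]) > 0:
            rho, _ = stats.spearmanr(d[mask], sub[i][mask])
            if not np.isnan(rho):
                rhos.append(rho)
    stat = float(np.mean(rhos)) if rhos else float("nan")
    df = pd.DataFrame(sub, index=list(ordered_ids), columns=list(ordered_ids))
    return df, stat


def plot_rf_heatmap(matrix: pd.DataFrame, path: str | Path,
                    title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.to_numpy(), cmap="viridis_r", vmin=0, vmax=0.5)
    ax.set_title(title or "pairwise recombination fraction")
    fig.colorbar(im, ax=ax, label="r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# segment assembly (translocation workflow) and map comparison


def assemble_segments(segments: Sequence[Sequence[str]], f2: F2Matrix,
                      ) -> tuple[list[str], dict[str, float]]:
    """Concatenate independently ordered segments and compute fixed-order
    distances.

    Used for chromosomes broken by a reciprocal translocation: each piece is
    ordered on its own, then joined in the given order/orientation and all
    adjacent distances — including across the junction — are computed by
    recombination-fraction MLE and the Kosambi function with no reordering.
    """
    flat: list[str] = []
    seen: set[str] = set()
    for seg in segments:
        for mk in seg:
            if mk in seen:
                raise ValueError(f"marker {mk!r} appears in more than one segment")
            seen.add(mk)
            flat.append(mk)
    index = {m: i for i, m in enumerate(f2.markers)}
    pos = {flat[0]: 0.0}
    total = 0.0
    for a, b in zip(flat[:-1], flat[1:]):
        pair = estimate_rf(f2.codes[index[a]], f2.codes[index[b]], a, b)
        r = min(pair.r_hat, 0.5 - _R_EPS)
        total += kosambi_cM(r)
        pos[b] = total
    return flat, pos


def map_correlation(map_a: GeneticMap, map_b: GeneticMap) -> float:
    """R^2 between two genetic maps over their shared markers.

    Positions are normalized per linkage group to [0, 1]; groups are matched
    by best reciprocal marker overlap and each matched group of map_b is
    flipped when its shared-marker positions run opposite to map_a.  Returns
    the squared Pearson correlation of the pooled normalized positions.
    """
    shared_total = set(map_a.positions) & set(map_b.positions)
    if len(shared_total) < 3:
        raise ValueError("need at least 3 shared markers")

    def _norm(gmap: GeneticMap) -> dict[str, tuple[int, float]]:
        out = {}
        for gi, g in enumerate(gmap.groups):
            lo = min(gmap.positions[m] for m in g)
            hi = max(gmap.positions[m] for m in g)
            span = hi - lo
            for m in g:
                x = 0.0 if span == 0 else (gmap.positions[m] - lo) / span
                out[m] = (gi, x)
        return out

    na, nb = _norm(map_a), _norm(map_b)
    overlap: dict[tuple[int, int], list[str]] = {}
    for m in shared_total:
        key = (na[m][0], nb[m][0])
        overlap.setdefault(key, []).append(m)
    used_a: set[int] = set()
    used_b: set[int] = set()
    xs, ys = [], []
    for (ga, gb), markers in sorted(overlap.items(),
                                    key=lambda kv: (-len(kv[1]), kv[0])):
        if ga in used_a or gb in used_b:
            continue
        used_a.add(ga)
        used_b.add(gb)
        xa = np.array([na[m][1] for m in markers])
        xb = np.array([nb[m][1] for m in markers])
        if len(markers) >= 2 and np.corrcoef(xa, xb)[0, 1] < 0:
            xb = 1.0 - xb
        xs.append(xa)
        ys.append(xb)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size < 3:
        raise ValueError("need at least 3 shared markers in matched groups")
    if np.std(x) == 0 or np.std(y) == 0:
        return 1.0 if np.allclose(x, y) else 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


# ---------------------------------------------------------------------------
# high-level map construction


@dataclass
class MapBuild:
    """A built map plus the pairwise statistics used to build it."""

    gmap: GeneticMap
    R: np.ndarray
    LOD: np.ndarray
    marker_index: dict[str, int] = field(default_factory=dict)


def build_map(f2: F2Matrix, lod_min: float = 3.0, r_max: float = 0.4,
              criterion: str = "lod", min_group_size: int = 2,
              bin_min_shared: int = 1,
              anchors: Mapping[int, str] | None = None) -> MapBuild:
    """Full map construction: pairwise rf -> grouping -> ordering -> bins.

    ``anchors`` optionally maps group number (0-based, in output order) to a
    marker id used to orient that group.  Groups smaller than
    ``min_group_size`` are kept as trailing singleton groups.
    """
    R, LOD, _ = pairwise_rf(f2.codes)
    index = {m: i for i, m in enumerate(f2.markers)}
    groups = group_markers(R, LOD, f2.markers, lod_min=lod_min, r_max=r_max,
                           criterion=criterion)
    ordered_groups: list[list[str]] = []
    positions: dict[str, float] = {}
    bins: dict[str, int] = {}
    next_bin = 0
    for gi, g in enumerate(groups):
        anchor = anchors.get(gi) if anchors else None
        sub_idx = [index[m] for m in g]
        sub_R = R[np.ix_(sub_idx, sub_idx)]
        ordered = order_markers(g, sub_R, anchor=anchor)
        ordered_groups.append(ordered)
        positions.update(map_positions(ordered, R, index))
        code_rows = np.array([index[m] for m in ordered])
        b = collapse_bins(f2.codes[code_rows], min_shared=bin_min_shared)
        for mk, bid in zip(ordered, b):
            bins[mk] = next_bin + int(bid)
        next_bin += int(b[-1]) + 1
    gmap = GeneticMap(ordered_groups, positions, bins)
    return MapBuild(gmap, R, LOD, index)
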