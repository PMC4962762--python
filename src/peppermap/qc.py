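"""Array-genotype quality control.

Per-marker call frequency, failed/functional and monomorphic/polymorphic
status, minor allele frequency, and the three summary spectra a genotyping
array is validated with: call-frequency classes, cluster-quality (GenTrain)
tiers for polymorphic markers, and the MAF spectrum in 0.05-wide bins.

Cluster scores are accepted as input (the clustering algorithm itself is
proprietary and upstream of this module).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING_GT = "--"


@dataclass
class ArrayGenotypes:
    """Marker x sample diploid calls, with optional per-marker cluster score."""

    calls: pd.DataFrame  # markers x samples, "AA"/"AB"/"--"
    cluster_score: pd.Series | None = None  # per-marker, in [0, 1]

    def __post_init__(self) -> None:
        if self.cluster_score is not None:
            cs = self.cluster_score.dropna()
            if ((cs < 0) | (cs > 1)).any():
                raise ValueError("cluster scores must be in [0, 1]")

    @property
    def markers(self) -> list[str]:
        return list(self.calls.index.astype(str))

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns.astype(str))


@dataclass(frozen=True)
class MarkerQC:
    marker: str
    call_frequency: float
    status: str  # "failed" | "functional"
    polymorphism: str  # "monomorphic" | "polymorphic" | "n/a"
    maf: float
    n_called: int


def qc_marker(calls: Iterable[str], marker: str = "") -> MarkerQC:
    """QC one marker's calls across samples.

    Call frequency is the fraction of samples with a genotype; a marker
    that calls no sample at all is 'failed'.  A functional marker is
    polymorphic when at least two distinct genotypes occur; MAF counts each
    heterozygote allele once, over 2 x called samples.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("qc_marker needs at least one sample")
    called = [c for c in calls if c != MISSING_GT and not pd.isna(c)]
    cf = len(called) / len(calls)
    if not called:
        return MarkerQC(marker, 0.0, "failed", "n/a", float("nan"), 0)
    poly = "polymorphic" if len(set(called)) >= 2 else "monomorphic"
    alleles = Counter("".join(called))
    if len(alleles) < 2:
        maf = 0.0
    else:
        maf = min(alleles.values()) / (2 * len(called))
    return MarkerQC(marker, cf, "functional", poly, maf, len(called))


def qc_all(geno: ArrayGenotypes) -> list[MarkerQC]:
    return [qc_marker(row, marker=str(mk))
            for mk, row in zip(geno.calls.index, geno.calls.to_numpy())]


def _call_frequency_class(cf: float) -> str:
    # four disjoint classes; boundary values go to the higher class and an
    # exact 1.000 is its own class
    if cf == 1.0:
        return "1.000"
    if cf >= 0.980:
        return "0.980-0.999"
    if cf >= 0.750:
        return "0.750-0.980"
    return "0.000-0.750"


def _gentrain_tier(score: float) -> str:
    if score < 0.2:
        return "<0.2"
    if score < 0.3:
        return "<0.3"
    if score < 0.6:
        return "<0.6"
    if score < 0.8:
        return "<0.8"
    return ">0.8"


_CF_CLASSES = ["0.000-0.750", "0.750-0.980", "0.980-0.999", "1.000"]
_GT_TIERS = ["<0.2", "<0.3", "<0.6", "<0.8", ">0.8"]
_MAF_BINS = [f"{lo:.2f}-{lo + 0.05:.2f}" for lo in np.arange(0, 0.5, 0.05)]


def _maf_bin(maf: float) -> str:
    if not 0 <= maf <= 0.5:
        raise ValueError("MAF outside [0, 0.5]")
    i = min(int(maf / 0.05), 9)
    return _MAF_BINS[i]


def _spectrum(values: Sequence[str], order: Sequence[str]) -> pd.DataFrame:
    counts = Counter(values)
    df = pd.DataFrame({"count": [counts.get(k, 0) for k in order]},
                      index=list(order))
    total = df["count"].sum()
    df["percentage"] = (100.0 * df["count"] / total).round(2) if total else 0.0
    return df


def summarize_qc(qcs: Sequence[MarkerQC],
                 cluster_score: pd.Series | None = None
                 ) -> dict[str, pd.DataFrame]:
    """Validation summary tables.

    Returns spectra keyed "call_frequency" (all markers), "gentrain"
    (polymorphic markers with a cluster score; tiers <0.2, [0.2,0.3),
    [0.3,0.6), [0.6,0.8), >=0.8) and "maf" (polymorphic markers, ten
    0.05-wide bins over [0, 0.5]).  Counts per table sum to the number of
    markers it covers; percentages sum to 100 within rounding.
    """
    for q in qcs:
        if not 0 <= q.call_frequency <= 1:
            raise ValueError("call frequency outside [0, 1]")
    out = {"call_frequency": _spectrum(
        [_call_frequency_class(q.call_frequency) for q in qcs], _CF_CLASSES)}
    poly = [q for q in qcs if q.polymorphism == "polymorphic"]
    if cluster_score is not None:
        scores = [float(cluster_score[q.marker]) for q in poly
                  if q.marker in cluster_score.index]
        out["gentrain"] = _spectrum([_gentrain_tier(s) for s in scores],
                                    _GT_TIERS)
    out["maf"] = _spectrum([_maf_bin(q.maf) for q in poly], _MAF_BINS)
    return out


def status_counts(qcs: Sequence[MarkerQC]) -> dict[str, int]:
    """failed / functional / monomorphic / polymorphic marker counts."""
    failed = sum(q.status == "failed" for q in qcs)
    functional = len(qcs) - failed
    mono = sum(q.polymorphism == "monomorphic" for q in qcs)
    poly = sum(q.polymorphism == "polymorphic" for q in qcs)
    return {"total": len(qcs), "failed": failed, "functional": functional,
            "monomorphic": mono, "polymorphic": poly}


def maf_threshold_counts(qcs: Sequence[MarkerQC],
                         thresholds: Sequence[float]) -> dict[float, int]:
    """Counts of polymorphic markers with MAF strictly above each threshold."""
    for t in thresholds:
        if not 0 <= t < 0.5:
            raise ValueError("thresholds must be in [0, 0.5)")
    mafs = np.array([q.maf for q in qcs if q.polymorphism == "polymorphic"])
    return {float(t): int((mafs > t).sum()) for t in thresholds}


def qc_frame(qcs: Sequence[MarkerQC]) -> pd.DataFrame:
    return pd.DataFrame([{
        "marker": q.marker, "call_frequency": round(q.call_frequency, 4),
        "status": q.status, "polymorphism": q.polymorphism,
        "maf": round(q.maf, 4) if not np.isnan(q.maf) else np.nan,
        "n_called": q.n_called,
    } for q in qcs]).set_index("marker")
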