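"""Copy-number segmentation, aberration calling, cross-region comparison,
and reconciliation of mutation heterogeneity with copy-number state.

Segmentation is recursive binary splitting on binned log2 tumor/normal
ratios: the split maximising the Welch t statistic between the flanking
means is accepted while |t| clears a threshold and both sides keep a
minimum number of bins.  Gain/loss calls are simple log2 thresholds tuned
for single-copy events at moderate purity.

``reconcile_vaf`` asks whether apparent branch mutations on a chromosome
reflect a deletion (mutations gone entirely — LOH removed the mutant
allele) or a subclonal mixture (mutations present but at depressed VAF
relative to trunk mutations on the same chromosome).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._stats import rank_sum_test
from .clonality import BRANCH, TRUNK, ClonalAnnotation
from .variant_io import RegionCallMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CNASegment",
    "VafReconciliation",
    "segment",
    "call_segments",
    "compare_regions",
    "reconcile_vaf",
]


@dataclass(frozen=True)
class CNASegment:
    """A per-region genomic interval (0-based half-open) with a log2 ratio."""

    region_id: str
    chrom: str
    start: int
    end: int
    n_bins: int
    log2_ratio: float
    call: str = "neutral"  # gain | loss | neutral

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty segment [{self.start}, {self.end})")
        if self.call not in ("gain", "loss", "neutral"):
            raise ValueError(f"unknown call {self.call!r}")

    def overlaps(self, chrom: str, start: int, end: int) -> int:
        if chrom != self.chrom:
            return 0
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass(frozen=True)
class VafReconciliation:
    region_id: str
    chrom: str
    class_compared: str
    median_vaf_branch: float
    median_vaf_trunk: float
    rank_sum_p: float
    verdict: str  # loh_removed | subclonal_mixture | concordant | insufficient_data
    n_branch: int = 0
    n_trunk: int = 0
    fraction_branch_absent: float = 0.0


# ---------------------------------------------------------------------------
# segmentation


def _welch_t_splits(x: np.ndarray, min_bins: int) -> tuple[int, float]:
    """Best split index k (left = x[:k]) and its |Welch t|; (-1, 0) if none."""
    n = x.size
    if n < 2 * min_bins:
        return -1, 0.0
    ks = np.arange(min_bins, n - min_bins + 1)
    c1 = np.cumsum(x)
    c2 = np.cumsum(x * x)
    n1 = ks.astype(float)
    n2 = n - n1
    s1 = c1[ks - 1]
    s2 = c1[-1] - s1
    m1 = s1 / n1
    m2 = s2 / n2
    q1 = c2[ks - 1]
    q2 = c2[-1] - q1
    var1 = np.maximum(q1 - n1 * m1 * m1, 0.0) / np.maximum(n1 - 1, 1)
    var2 = np.maximum(q2 - n2 * m2 * m2, 0.0) / np.maximum(n2 - 1, 1)
    se = np.sqrt(var1 / n1 + var2 / n2)
    diff = np.abs(m1 - m2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, np.where(diff > 0, np.inf, 0.0))
    best = int(np.argmax(t))
    return int(ks[best]), float(t[best])


def segment(
    bins: pd.DataFrame,
    t_threshold: float = 5.0,
    min_bins: int = 10,
) -> list[CNASegment]:
    """Segment per-region binned log2 ratios by recursive binary splitting.

    ``bins`` needs columns region_id, chrom, start, end, log2 with bins
    ordered by genomic position within each chromosome (internal 0-based
    half-open coordinates).  Chromosomes with fewer than ``2 * min_bins``
    bins yield a single segment.  Segments tile each chromosome exactly.
    """
    required = {"region_id", "chrom", "start", "end", "log2"}
    missing = required - set(bins.columns)
    if missing:
        raise ValueError(f"bins frame missing columns: {sorted(missing)}")

    segments: list[CNASegment] = []
    for (region, chrom), grp in bins.groupby(["region_id", "chrom"], sort=True):
        grp = grp.sort_values("start")
        x = grp["log2"].to_numpy(dtype=float)
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)

        def recurse(lo: int, hi: int) -> None:
            k, t = _welch_t_splits(x[lo:hi], min_bins)
            if k >= 0 and t >= t_threshold:
                recurse(lo, lo + k)
                recurse(lo + k, hi)
            else:
                segments.append(
                    CNASegment(
                        region_id=str(region), chrom=str(chrom),
                        start=int(starts[lo]), end=int(ends[hi - 1]),
                        n_bins=hi - lo, log2_ratio=float(np.mean(x[lo:hi])),
                    )
                )

        recurse(0, x.size)
    return segments


def call_segments(
    segments: list[CNASegment],
    gain_thresh: float = 0.2,
    loss_thresh: float = -0.2,
) -> list[CNASegment]:
    """Threshold segment means into gain / loss / neutral calls."""
    if loss_thresh >= gain_thresh:
        raise ValueError("loss threshold must be below gain threshold")
    called = []
    for s in segments:
        if s.log2_ratio >= gain_thresh:
            call = "gain"
        elif s.log2_ratio <= loss_thresh:
            call = "loss"
        else:
            call = "neutral"
        called.append(replace(s, call=call))
    return called


def compare_regions(segments: list[CNASegment], loci: pd.DataFrame) -> pd.DataFrame:
    """Shared vs heterogeneous aberrations at loci of interest.

    ``loci`` needs columns chrom, start, end, name (0-based half-open, BED
    convention).  For each locus and region the call of the maximally
    overlapping segment is taken; an aberration carried by a proper
    nonempty subset of regions is flagged heterogeneous.  Loci with no
    aberration in any region contribute no rows.
    """
    required = {"chrom", "start", "end", "name"}
    if required - set(loci.columns):
        raise ValueError(f"loci frame needs columns {sorted(required)}")
    regions = sorted({s.region_id for s in segments})
    rows = []
    for _, locus in loci.iterrows():
        chrom, start, end = str(locus["chrom"]), int(locus["start"]), int(locus["end"])
        per_region_call: dict[str, str] = {}
        covered_anywhere = False
        for region in regions:
            overlapping = [
                (s.overlaps(chrom, start, end), s)
                for s in segments
                if s.region_id == region and s.overlaps(chrom, start, end) > 0
            ]
            if not overlapping:
                continue
            covered_anywhere = True
            _, best = max(overlapping, key=lambda t: t[0])
            per_region_call[region] = best.call
        if not covered_anywhere:
            raise ValueError(f"locus {locus['name']} ({chrom}:{start}-{end}) is "
                             "outside the covered genome")
        for call in ("gain", "loss"):
            carriers = sorted(r for r, c in per_region_call.items() if c == call)
            if not carriers:
                continue
            status = "shared" if len(carriers) == len(regions) else "heterogeneous"
            rows.append(
                (str(locus["name"]), chrom, start, end, call,
                 ",".join(carriers), len(carriers), status)
            )
    return pd.DataFrame(
        rows,
        columns=["locus", "chrom", "start", "end", "call", "regions",
                 "n_regions", "status"],
    )


# ---------------------------------------------------------------------------
# VAF reconciliation


def reconcile_vaf(
    matrix: RegionCallMatrix,
    annotations: list[ClonalAnnotation],
    chrom: str,
    region: str,
    min_mutations: int = 3,
    absent_fraction_loh: float = 0.8,
    alpha: float = 0.05,
) -> VafReconciliation:
    """Explain branch mutations on one chromosome in one region.

    Verdicts: ``loh_removed`` when at least ``absent_fraction_loh`` of the
    chromosome's branch mutations are absent from the region (the mutant
    allele was deleted); ``subclonal_mixture`` when they are present but at
    significantly lower VAF than trunk mutations on the same chromosome
    (two-sided rank-sum, exact for small groups); ``concordant`` otherwise.
    """
    j = matrix.region_index(region)
    present = matrix.present
    vaf = matrix.vaf
    branch_idx = [
        a.variant_index
        for a in annotations
        if a.clonal_class == BRANCH and matrix.variants[a.variant_index].chrom == chrom
    ]
    trunk_idx = [
        a.variant_index
        for a in annotations
        if a.clonal_class == TRUNK and matrix.variants[a.variant_index].chrom == chrom
    ]
    if len(branch_idx) < min_mutations or len(trunk_idx) < min_mutations:
        return VafReconciliation(
            region_id=region, chrom=chrom, class_compared="branch-vs-trunk",
            median_vaf_branch=float("nan"), median_vaf_trunk=float("nan"),
            rank_sum_p=float("nan"), verdict="insufficient_data",
            n_branch=len(branch_idx), n_trunk=len(trunk_idx),
        )

    absent = [i for i in branch_idx if not present[i, j]]
    frac_absent = len(absent) / len(branch_idx)
    branch_vafs = np.array([vaf[i, j] for i in branch_idx if present[i, j]])
    trunk_vafs = np.array([vaf[i, j] for i in trunk_idx if present[i, j]])

    if frac_absent >= absent_fraction_loh:
        return VafReconciliation(
            region_id=region, chrom=chrom, class_compared="branch-vs-trunk",
            median_vaf_branch=float(np.median(branch_vafs)) if branch_vafs.size else 0.0,
            median_vaf_trunk=float(np.median(trunk_vafs)) if trunk_vafs.size else 0.0,
            rank_sum_p=float("nan"), verdict="loh_removed",
            n_branch=len(branch_idx), n_trunk=len(trunk_idx),
            fraction_branch_absent=frac_absent,
        )

    if branch_vafs.size < min_mutations or trunk_vafs.size < min_mutations:
        return VafReconciliation(
            region_id=region, chrom=chrom, class_compared="branch-vs-trunk",
            median_vaf_branch=float(np.median(branch_vafs)) if branch_vafs.size else 0.0,
            median_vaf_trunk=float(np.median(trunk_vafs)) if trunk_vafs.size else 0.0,
            rank_sum_p=float("nan"), verdict="insufficient_data",
            n_branch=len(branch_idx), n_trunk=len(trunk_idx),
            fraction_branch_absent=frac_absent,
        )

    res = rank_sum_test(branch_vafs, trunk_vafs)
    lower = res["median_x"] < res["median_y"]
    verdict = "subclonal_mixture" if (res["p"] < alpha and lower) else "concordant"
    return VafReconciliation(
        region_id=region, chrom=chrom, class_compared="branch-vs-trunk",
        median_vaf_branch=res["median_x"], median_vaf_trunk=res["median_y"],
        rank_sum_p=res["p"], verdict=verdict,
        n_branch=len(branch_idx), n_trunk=len(trunk_idx),
        fraction_branch_absent=frac_absent,
    )
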