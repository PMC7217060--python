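"""Presence/absence calling with cross-region rescue and purity-based
region exclusion.

Multi-region calling is asymmetric by design: declaring a mutation de novo
in a region demands solid evidence, but once a mutation is established in
any region, a lower bar suffices to accept it in the others ("rescue").
This prevents sampling noise from fabricating heterogeneity — the failure
mode multi-region studies worry about most, since apparent branch/private
mutations are often just coverage or purity artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .variant_io import PresenceStatus, RegionCallMatrix

logger = logging.getLogger(__name__)

__all__ = ["CallThresholds", "PurityEstimate", "call_presence", "estimate_purity",
           "drop_excluded"]


@dataclass(frozen=True)
class CallThresholds:
    """Evidence thresholds for presence calling and region exclusion.

    Defaults are conservative for ~70-130x exome coverage: a cell needs 30
    reads to be evaluable at all, 3 alt reads at >=2% VAF to establish a
    mutation de novo, and 2 alt reads to confirm a mutation already seen
    elsewhere.  Regions below 20% estimated tumor content are excluded.
    """

    min_depth_evaluable: int = 30
    min_alt_denovo: int = 3
    min_vaf_denovo: float = 0.02
    min_alt_rescue: int = 2
    min_purity: float = 0.2

    def __post_init__(self) -> None:
        if self.min_alt_rescue > self.min_alt_denovo:
            raise ValueError("min_alt_rescue must be <= min_alt_denovo")
        for name in ("min_vaf_denovo", "min_purity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_depth_evaluable < 1 or self.min_alt_denovo < 1:
            raise ValueError("read-count thresholds must be positive")


@dataclass(frozen=True)
class PurityEstimate:
    region_id: str
    purity: float
    n_support: int
    excluded: bool
    low_support: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.purity <= 1.0):
            raise ValueError(f"purity {self.purity} outside [0, 1]")


def call_presence(
    matrix: RegionCallMatrix, thresholds: CallThresholds | None = None
) -> RegionCallMatrix:
    """Assign present/absent/indeterminate to every cell of the matrix.

    Per cell: depth below ``min_depth_evaluable`` -> indeterminate; else
    present when alt reads and VAF clear the de novo thresholds; else
    present (rescued) when the variant is de novo present in at least one
    other region and the cell still has ``min_alt_rescue`` alt reads; else
    absent.  Idempotent: statuses are recomputed from counts alone.
    """
    thresholds = thresholds or CallThresholds()
    out = matrix.copy()
    depth, alt = out.depth, out.alt
    vaf = out.vaf

    evaluable = depth >= thresholds.min_depth_evaluable
    denovo = evaluable & (alt >= thresholds.min_alt_denovo) & (vaf >= thresholds.min_vaf_denovo)
    denovo_anywhere = denovo.any(axis=1)
    rescued = (
        evaluable
        & ~denovo
        & denovo_anywhere[:, None]
        & (alt >= thresholds.min_alt_rescue)
    )

    status = np.full(depth.shape, PresenceStatus.ABSENT, dtype=np.int8)
    status[~evaluable] = PresenceStatus.INDETERMINATE
    status[denovo] = PresenceStatus.PRESENT
    status[rescued] = PresenceStatus.PRESENT_RESCUED
    out.status = status
    return out


def estimate_purity(
    matrix: RegionCallMatrix,
    segments=None,
    thresholds: CallThresholds | None = None,
    ubiquity: float = 0.9,
    min_support: int = 10,
) -> list[PurityEstimate]:
    """Estimate per-region tumor purity from near-ubiquitous variants.

    Variants present in at least ``ubiquity`` of regions serve as trunk
    proxies (classification does not exist yet at this stage — the >=90%
    presence heuristic breaks the circularity).  Under the
    heterozygous-diploid assumption each trunk mutation sits on one of two
    copies in every tumor cell, so purity = 2 x median VAF, capped at 1.
    Only copy-neutral territory is used when segments are supplied.
    """
    thresholds = thresholds or CallThresholds()
    present = matrix.present
    n_reg = matrix.n_regions
    frac_present = present.sum(axis=1) / max(n_reg, 1)
    ubiquitous = frac_present >= ubiquity

    neutral_mask = _neutral_mask(matrix, segments)

    estimates = []
    vaf = matrix.vaf
    for j, region in enumerate(matrix.regions):
        use = ubiquitous & present[:, j] & neutral_mask[:, j]
        n_support = int(use.sum())
        low_support = n_support < min_support
        if low_support:
            logger.warning(
                "purity estimate for %s rests on only %d variants", region, n_support
            )
        med = float(np.median(vaf[use, j])) if n_support else 0.0
        purity = min(1.0, 2.0 * med)
        estimates.append(
            PurityEstimate(
                region_id=region,
                purity=purity,
                n_support=n_support,
                excluded=purity < thresholds.min_purity,
                low_support=low_support,
            )
        )
    return estimates


def _neutral_mask(matrix: RegionCallMatrix, segments) -> np.ndarray:
    """Boolean (variant, region) grid: True where copy-neutral (or unknown)."""
    mask = np.ones((matrix.n_variants, matrix.n_regions), dtype=bool)
    if not segments:
        return mask
    by_region: dict[str, list] = {}
    for s in segments:
        if s.call in ("gain", "loss"):
            by_region.setdefault(s.region_id, []).append(s)
    for j, region in enumerate(matrix.regions):
        aberrant = by_region.get(region, [])
        if not aberrant:
            continue
        for i, v in enumerate(matrix.variants):
            p0 = v.pos - 1  # internal 0-based
            for s in aberrant:
                if s.chrom == v.chrom and s.start <= p0 < s.end:
                    mask[i, j] = False
                    break
    return mask


def drop_excluded(
    matrix: RegionCallMatrix, purities: list[PurityEstimate]
) -> RegionCallMatrix:
    """Remove excluded regions; drop variants left present nowhere.

    Dropping a low-purity region can strand variants that were only ever
    seen there; those rows are removed (and logged) because a variant
    present in zero retained regions carries no information downstream.
    """
    excluded = {p.region_id for p in purities if p.excluded}
    keep_regions = [r for r in matrix.regions if r not in excluded]
    if not keep_regions:
        raise ValueError("all regions excluded by the purity filter")
    out = matrix.subset_regions(keep_regions)
    present_somewhere = out.present.any(axis=1)
    n_dropped = int((~present_somewhere).sum())
    if n_dropped:
        logger.info(
            "dropped %d variants present only in excluded regions %s",
            n_dropped, sorted(excluded),
        )
        out = out.subset_variants(np.flatnonzero(present_somewhere))
    return out
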