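"""Substitution spectra, dinucleotide variants (DNVs), and UV attribution.

Substitutions are reduced to the pyrimidine strand, giving six base
classes; C>T — the UV workhorse — is further split by the 5' neighbour
(purine R vs pyrimidine Y) and whether the 3' neighbour is G.  UV
photoproducts form at dipyrimidine sites, so C>T with a 5' pyrimidine
(the two YC>T groups) is counted as UV-attributable, as are CC>TT tandem
substitutions among DNVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._stats import fisher_exact_2x2, mc_fisher_2xk
from .variant_io import RegionCallMatrix, SomaticVariant

logger = logging.getLogger(__name__)

__all__ = [
    "SNV_CATEGORIES",
    "UV_CATEGORIES",
    "SubstitutionSpectrum",
    "DNVEvent",
    "canonicalize",
    "detect_dnvs",
    "build_spectrum",
    "uv_fraction",
    "compare_spectra",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SNV_CATEGORIES = (
    "C>A", "C>G", "T>A", "T>C", "T>G",
    "RC>T,+G", "RC>T,-G", "YC>T,+G", "YC>T,-G",
)
UV_CATEGORIES = ("YC>T,+G", "YC>T,-G")
UNCLASSIFIABLE = "unclassifiable"

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonicalize(variant: SomaticVariant) -> tuple[str, str, str]:
    """Reduce an SNV to the pyrimidine strand and name its category.

    Returns ``(substitution, context, category)`` where substitution is
    e.g. ``"C>T"``, context is the (possibly reverse-complemented) 3-mer,
    and category is one of SNV_CATEGORIES or ``"unclassifiable"`` when the
    context contains an ambiguous base or is missing.
    """
    if not variant.is_snv:
        raise ValueError(f"canonicalize expects an SNV, got {variant.ref}>{variant.alt}")
    ref, alt, ctx = variant.ref, variant.alt, variant.tri_context
    if ref in _PURINES:
        ref, alt = _revcomp(ref), _revcomp(alt)
        ctx = _revcomp(ctx) if ctx else ""
    sub = f"{ref}>{alt}"
    if not ctx or "N" in ctx or ref not in "CT":
        return sub, ctx, UNCLASSIFIABLE
    if sub != "C>T":
        return sub, ctx, sub
    five, three = ctx[0], ctx[2]
    if five in _PURINES:
        group5 = "R"
    elif five in _PYRIMIDINES:
        group5 = "Y"
    else:
        return sub, ctx, UNCLASSIFIABLE
    group3 = "+G" if three == "G" else "-G"
    return sub, ctx, f"{group5}C>T,{group3}"


@dataclass(frozen=True)
class DNVEvent:
    """Two adjacent SNVs behaving as a single mutational event."""

    chrom: str
    pos: int  # first base, 1-based
    ref_dinuc: str
    alt_dinuc: str
    member_indices: tuple[int, int]
    canonical: bool = True  # stored orientation is the pyrimidine strand

    @property
    def is_cc_tt(self) -> bool:
        return (self.ref_dinuc, self.alt_dinuc) in (("CC", "TT"), ("GG", "AA"))


@dataclass
class SubstitutionSpectrum:
    """Counts over the nine SNV categories plus DNV bookkeeping."""

    counts: dict = field(default_factory=lambda: {c: 0 for c in SNV_CATEGORIES})
    unclassifiable: int = 0
    dnv_count: int = 0
    cc_tt_count: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()) or min(
            self.unclassifiable, self.dnv_count, self.cc_tt_count
        ) < 0:
            raise ValueError("spectrum counts must be non-negative")
        if self.cc_tt_count > self.dnv_count:
            raise ValueError("CC>TT count cannot exceed DNV count")

    @property
    def total_snv(self) -> int:
        return sum(self.counts.values())

    @property
    def total_c_to_t(self) -> int:
        return sum(self.counts[c] for c in SNV_CATEGORIES if "C>T" in c)

    @property
    def total_classified(self) -> int:
        """SNV categories plus DNV events (each DNV is one unit)."""
        return self.total_snv + self.dnv_count

    @property
    def uv_attributable(self) -> int:
        return sum(self.counts[c] for c in UV_CATEGORIES) + self.cc_tt_count


def detect_dnvs(matrix: RegionCallMatrix, vaf_ratio_max: float = 2.0) -> list[DNVEvent]:
    """Merge adjacent-position SNV pairs into DNV events.

    Two SNVs are merged when they sit at consecutive positions on the same
    chromosome, have identical presence patterns across regions (cells
    where either member is indeterminate are ignored: a coverage hole is
    not a discordant call), and their VAFs agree within ``vaf_ratio_max``
    in every region where both are present.  Runs of three or more
    consecutive mutated positions are merged pairwise left to right (with
    a warning).  A determinate presence-pattern mismatch leaves two
    independent SNVs — discordant calls must not fabricate trunk DNVs.
    """
    from .variant_io import PresenceStatus

    present = matrix.present
    indeterminate = matrix.status == PresenceStatus.INDETERMINATE
    vaf = matrix.vaf
    snv_idx = [i for i, v in enumerate(matrix.variants) if v.is_snv]
    order = sorted(snv_idx, key=lambda i: (matrix.variants[i].chrom, matrix.variants[i].pos))

    events: list[DNVEvent] = []
    used: set[int] = set()
    for a, b in zip(order, order[1:]):
        va, vb = matrix.variants[a], matrix.variants[b]
        if va.chrom != vb.chrom or vb.pos != va.pos + 1:
            continue
        if a in used:
            logger.warning(
                "three or more consecutive mutated positions at %s:%d; merging "
                "pairwise left to right", va.chrom, va.pos,
            )
            continue
        comparable = ~(indeterminate[a] | indeterminate[b])
        if not np.array_equal(present[a] & comparable, present[b] & comparable):
            continue
        both = present[a] & present[b]
        ok = True
        for j in np.flatnonzero(both):
            lo, hi = sorted((vaf[a, j], vaf[b, j]))
            if lo <= 0 or hi / lo > vaf_ratio_max:
                ok = False
                break
        if not ok:
            continue
        ref_d, alt_d = va.ref + vb.ref, va.alt + vb.alt
        canonical = not (ref_d[0] in _PURINES and ref_d[1] in _PURINES)
        events.append(
            DNVEvent(
                chrom=va.chrom, pos=va.pos, ref_dinuc=ref_d, alt_dinuc=alt_d,
                member_indices=(a, b), canonical=canonical,
            )
        )
        used.update((a, b))
    return events


def build_spectrum(
    matrix: RegionCallMatrix,
    variant_indices=None,
    dnv_events: list[DNVEvent] | None = None,
) -> SubstitutionSpectrum:
    """Spectrum over a variant subset (e.g. trunk, or one region's calls).

    DNV members are counted once, through their event, and only when both
    members belong to the subset; indels are skipped (the spectrum concerns
    substitutions only).
    """
    if variant_indices is None:
        variant_indices = range(matrix.n_variants)
    subset = set(variant_indices)
    dnv_events = dnv_events or []
    member_of = {i: ev for ev in dnv_events for i in ev.member_indices}

    spec = SubstitutionSpectrum()
    counted_events: set[tuple] = set()
    for i in sorted(subset):
        v = matrix.variants[i]
        if not v.is_snv:
            continue
        ev = member_of.get(i)
        if ev is not None and all(m in subset for m in ev.member_indices):
            key = ev.member_indices
            if key in counted_events:
                continue
            counted_events.add(key)
            spec.dnv_count += 1
            if ev.is_cc_tt:
                spec.cc_tt_count += 1
            continue
        _, _, category = canonicalize(v)
        if category == UNCLASSIFIABLE:
            spec.unclassifiable += 1
        else:
            spec.counts[category] += 1
    return spec


def uv_fraction(spectrum: SubstitutionSpectrum) -> float:
    """Fraction of classified substitution events attributable to UV.

    UV-attributable = dipyrimidine-context C>T (the two YC>T groups) plus
    CC>TT DNV events; the denominator counts every classified SNV plus
    every DNV event once.
    """
    total = spectrum.total_classified
    if total == 0:
        raise ValueError("UV fraction is undefined on an empty spectrum")
    return spectrum.uv_attributable / total


def compare_spectra(
    spec_a: SubstitutionSpectrum,
    spec_b: SubstitutionSpectrum,
    n_permutations: int = 100_000,
    seed: int | None = 0,
) -> dict:
    """Compare two spectra: 2x2 UV vs non-UV, and full 2xk distribution.

    The 2x2 comparison (UV-attributable vs the rest) is the exact two-sided
    Fisher test.  The full-spectrum comparison uses the nine SNV categories
    plus CC>TT and non-CC>TT DNVs as columns and a seeded Monte-Carlo
    Fisher test (tables sampled from the fixed-margin null); categories
    empty in both spectra are dropped first.
    """
    for name, s in (("first", spec_a), ("second", spec_b)):
        if s.total_classified == 0:
            raise ValueError(f"{name} spectrum is empty")
    uv_a, uv_b = spec_a.uv_attributable, spec_b.uv_attributable
    table22 = np.array(
        [
            [uv_a, spec_a.total_classified - uv_a],
            [uv_b, spec_b.total_classified - uv_b],
        ]
    )
    p_uv = fisher_exact_2x2(table22)

    def row(s: SubstitutionSpectrum) -> list[int]:
        return [s.counts[c] for c in SNV_CATEGORIES] + [
            s.cc_tt_count,
            s.dnv_count - s.cc_tt_count,
        ]

    full = np.array([row(spec_a), row(spec_b)], dtype=np.int64)
    keep = full.sum(axis=0) > 0
    full = full[:, keep]
    p_full = mc_fisher_2xk(full, n_permutations=n_permutations, seed=seed)
    return {"p_uv_2x2": p_uv, "uv_table": table22, "p_full_2xk": p_full,
            "full_table": full}
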