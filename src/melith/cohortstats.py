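"""Cohort-level mutation-frequency and mutational-load statistics.

Operates on any cohort mutation table (one row per sample x mutated gene,
with CSD class and stage labels): per-gene mutation frequencies with
Fisher tests between strata, hotspot codon composition among mutant
samples, and rank-sum comparisons of per-sample mutational load.

Group comparisons of load use the unpaired Wilcoxon rank-sum
(Mann-Whitney) test: the strata are independent samples, so the paired
signed-rank test does not apply.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import fisher_exact_2x2, rank_sum_test
from .clonality import round_half_away

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSample",
    "cohort_from_table",
    "gene_freq_test",
    "codon_composition_test",
    "compare_load",
    "mutation_summary",
    "benjamini_hochberg",
]


@dataclass
class CohortSample:
    sample_id: str
    group: str  # CSD_high | CSD_low
    stage: str  # in_situ | invasive
    mutational_load: int
    gene_hits: set = field(default_factory=set)  # {(gene, protein_change)}

    def __post_init__(self) -> None:
        if self.mutational_load < 0:
            raise ValueError("mutational load must be >= 0")

    def has_gene(self, gene: str) -> bool:
        return any(g == gene for g, _ in self.gene_hits)


def cohort_from_table(df: pd.DataFrame) -> list[CohortSample]:
    """Aggregate a validated cohort TSV frame into per-sample records.

    Rows with an empty gene field only contribute sample metadata.  When a
    ``mutational_load`` column is present it is used; otherwise load
    defaults to the number of gene rows per sample (i.e. the panel hits).
    """
    samples: dict[str, CohortSample] = {}
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        if sid not in samples:
            load = int(row["mutational_load"]) if "mutational_load" in df.columns else 0
            samples[sid] = CohortSample(
                sample_id=sid, group=str(row["group"]), stage=str(row["stage"]),
                mutational_load=load,
            )
        gene = str(row.get("gene", "") or "")
        if gene:
            samples[sid].gene_hits.add((gene, str(row.get("protein_change", "") or "")))
    if "mutational_load" not in df.columns:
        for s in samples.values():
            s.mutational_load = len(s.gene_hits)
    return list(samples.values())


def _strata(cohort: list[CohortSample], by: str) -> tuple[str, str, list, list]:
    if by == "group":
        labels = ("CSD_high", "CSD_low")
        key = lambda s: s.group
    elif by == "stage":
        labels = ("in_situ", "invasive")
        key = lambda s: s.stage
    else:
        raise ValueError(f"unknown stratification {by!r}")
    a = [s for s in cohort if key(s) == labels[0]]
    b = [s for s in cohort if key(s) == labels[1]]
    if not a or not b:
        raise ValueError(f"both {labels} strata must be non-empty")
    return labels[0], labels[1], a, b


def gene_freq_test(cohort: list[CohortSample], gene: str, by: str = "group") -> dict:
    """2x2 mutant/wild-type counts between strata with two-sided Fisher p."""
    la, lb, a, b = _strata(cohort, by)
    ma = sum(1 for s in a if s.has_gene(gene))
    mb = sum(1 for s in b if s.has_gene(gene))
    table = np.array([[ma, len(a) - ma], [mb, len(b) - mb]], dtype=np.int64)
    if ma == 0 and mb == 0:
        logger.warning("gene %s absent from the cohort; p = 1", gene)
        p = 1.0
    else:
        p = fisher_exact_2x2(table)
    return {
        "gene": gene, "by": by, "strata": (la, lb), "table": table, "p": p,
        "freq": (ma / len(a), mb / len(b)),
    }


def codon_composition_test(
    cohort: list[CohortSample], gene: str, codon_classes: tuple[str, str],
    by: str = "group",
) -> dict:
    """Hotspot composition (e.g. V600E vs V600K) among gene-mutant samples."""
    if len(set(codon_classes)) < 2:
        raise ValueError("need two distinct codon classes to compare")
    la, lb, a, b = _strata(cohort, by)

    def count(samples, pchange):
        return sum(
            1 for s in samples if (gene, pchange) in s.gene_hits
        )

    table = np.array(
        [
            [count(a, codon_classes[0]), count(a, codon_classes[1])],
            [count(b, codon_classes[0]), count(b, codon_classes[1])],
        ],
        dtype=np.int64,
    )
    p = fisher_exact_2x2(table)  # degenerate margin -> p = 1 with warning
    return {"gene": gene, "classes": codon_classes, "strata": (la, lb),
            "table": table, "p": p}


def compare_load(cohort: list[CohortSample], by: str = "group") -> dict:
    """Two-sided rank-sum comparison of per-sample mutational load."""
    la, lb, a, b = _strata(cohort, by)
    loads_a = [s.mutational_load for s in a]
    loads_b = [s.mutational_load for s in b]
    res = rank_sum_test(loads_a, loads_b)
    return {
        "by": by, "strata": (la, lb), "n": (len(a), len(b)),
        "median": (res["median_x"], res["median_y"]),
        "U": res["U"], "p": res["p"], "method": res["method"],
    }


def mutation_summary(cohort: list[CohortSample]) -> pd.DataFrame:
    """Per-gene mutant-sample counts and percentages, with hotspot breakdown.

    Percentages are of the cohort for genes and of the gene-mutant subset
    for protein changes, rounded half-away-from-zero to integers.
    """
    if not cohort:
        raise ValueError("empty cohort")
    n = len(cohort)
    genes = sorted({g for s in cohort for g, _ in s.gene_hits})
    rows = []
    for gene in genes:
        mutant = [s for s in cohort if s.has_gene(gene)]
        rows.append((gene, "", len(mutant), int(round_half_away(100 * len(mutant) / n))))
        pchanges = sorted({p for s in mutant for g, p in s.gene_hits if g == gene and p})
        for pc in pchanges:
            k = sum(1 for s in mutant if (gene, pc) in s.gene_hits)
            rows.append(
                (gene, pc, k, int(round_half_away(100 * k / len(mutant))))
            )
    return pd.DataFrame(rows, columns=["gene", "protein_change", "n", "percent"])


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted q-values (available but off by default: the headline
    analyses report raw p-values)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * p.size / (np.arange(p.size) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(q)
    out[order] = np.minimum(q, 1.0)
    return out
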