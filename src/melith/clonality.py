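"""Trunk/branch/private classification and the mutation-based phylogeny.

A mutation present in every evaluable region is *trunk* (acquired before
the regions diverged), one confined to a single region is *private*, and
anything in between is *branch*.  Cells with too little coverage to judge
are ignored for the all-regions test rather than counted as absent, so
coverage holes cannot fabricate heterogeneity.

The phylogeny is a perfect-phylogeny-style parsimony tree over the binary
presence patterns: patterns are accepted greedily, by descending variant
support, as long as they stay pairwise nested-or-disjoint (a laminar
family, which is exactly the set of clades of a rooted tree).  Variants
whose pattern conflicts with the accepted family are homoplasy: they are
attached to the most similar accepted clade and reported, never dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .variant_io import PresenceStatus, RegionCallMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClonalAnnotation",
    "PhyloTree",
    "classify",
    "summarize_classes",
    "build_tree",
    "heterogeneity_enrichment",
    "round_half_away",
]

TRUNK, BRANCH, PRIVATE = "trunk", "branch", "private"


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round with halves going away from zero (printed-percentage convention)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class ClonalAnnotation:
    variant_index: int
    clonal_class: str  # trunk | branch | private
    region_set: frozenset
    n_evaluable: int


def classify(matrix: RegionCallMatrix) -> list[ClonalAnnotation]:
    """Annotate every variant as trunk, branch or private.

    Indeterminate cells do not participate in the all-regions test: trunk
    means present in every region where the variant was evaluable (with at
    least two evaluable regions).
    """
    if matrix.n_regions < 2:
        raise ValueError("classification needs at least 2 regions")
    present = matrix.present
    evaluable = matrix.status != PresenceStatus.INDETERMINATE
    annotations = []
    for i in range(matrix.n_variants):
        regions = frozenset(
            matrix.regions[j] for j in range(matrix.n_regions) if present[i, j]
        )
        n_eval = int(evaluable[i].sum())
        n_present = len(regions)
        if n_present == 0:
            raise ValueError(
                f"variant {matrix.variants[i].key} is present in no region; "
                "drop it upstream before classification"
            )
        if n_eval >= 2 and n_present == int((present[i] & evaluable[i]).sum()) == n_eval:
            cls = TRUNK
        elif n_present == 1:
            cls = PRIVATE
        else:
            cls = BRANCH
        annotations.append(ClonalAnnotation(i, cls, regions, n_eval))
    return annotations


def summarize_classes(
    annotations: list[ClonalAnnotation], decimals: int = 1
) -> dict[str, dict[str, float]]:
    """Counts and printed-style percentages per clonal class.

    Percentages are rounded half-away-from-zero to ``decimals``; counts are
    exact.  Also reports the pooled non-trunk ("heterogeneous") share.
    """
    if not annotations:
        raise ValueError("no annotations to summarize")
    total = len(annotations)
    out: dict[str, dict[str, float]] = {}
    for cls in (TRUNK, BRANCH, PRIVATE):
        n = sum(1 for a in annotations if a.clonal_class == cls)
        out[cls] = {
            "count": n,
            "percent": round_half_away(100.0 * n / total, decimals),
            "percent_raw": 100.0 * n / total,
        }
    n_het = total - out[TRUNK]["count"]
    out["heterogeneous"] = {
        "count": n_het,
        "percent": round_half_away(100.0 * n_het / total, decimals),
        "percent_raw": 100.0 * n_het / total,
    }
    out["total"] = {"count": total, "percent": 100.0, "percent_raw": 100.0}
    return out


# ---------------------------------------------------------------------------
# phylogeny


@dataclass
class PhyloTree:
    """Rooted mutation tree: leaves are regions, the root is normal tissue.

    Every node below the root corresponds to a clade (a region subset from
    the laminar family); its incoming edge carries the variants whose
    presence pattern equals that clade, so branch length = mutation count.
    """

    regions: list[str]
    clades: list[frozenset]  # accepted laminar family, includes all singletons + full set
    parent: dict  # clade -> parent clade (full set's parent is None == root/normal)
    edge_variants: dict  # clade -> list of variant indices assigned
    homoplasy: list  # (variant_index, observed pattern, assigned clade)

    @property
    def edge_counts(self) -> dict:
        return {c: len(v) for c, v in self.edge_variants.items()}

    @property
    def total_assigned(self) -> int:
        return sum(len(v) for v in self.edge_variants.values())

    def children(self, clade) -> list:
        kids = [c for c, p in self.parent.items() if p == clade]
        return sorted(kids, key=lambda c: (len(c), tuple(sorted(c))))

    def to_newick(self, trunk_display_length: int | None = None) -> str:
        """Newick with mutation-count branch lengths.

        ``trunk_display_length`` optionally caps the displayed trunk edge
        (a rendering convention for very long trunks); the underlying
        counts are untouched.
        """
        full = frozenset(self.regions)

        def render(clade) -> str:
            length = len(self.edge_variants.get(clade, []))
            if clade == full and trunk_display_length is not None:
                length = min(length, trunk_display_length)
            kids = self.children(clade)
            if len(clade) == 1 and not kids:
                (region,) = clade
                return f"{region}:{length}"
            inner = ",".join(render(k) for k in kids)
            return f"({inner}):{length}"

        return f"({render(full)})normal;"

    def parsimony_cost(self) -> int:
        """Total parsimony changes of all assigned variants on this tree.

        Each variant's binary presence pattern is scored with Fitch small
        parsimony (polytomies allowed); compatible patterns cost exactly 1,
        homoplasious ones more.
        """
        full = frozenset(self.regions)
        cost = 0
        pattern_of: dict[int, frozenset] = {}
        for clade, vids in self.edge_variants.items():
            for v in vids:
                pattern_of[v] = clade
        # homoplasious variants are scored on their observed pattern, not
        # the clade they were parked on
        for v, pattern, _assigned in self.homoplasy:
            pattern_of[v] = pattern
        for pat in pattern_of.values():
            cost += self._fitch(full, pat)
        return cost

    def _fitch(self, clade, pattern) -> int:
        """Minimum state changes for one binary character; the root
        (normal tissue) is fixed at absent.  Exact also on polytomies
        (Sankoff-style dynamic programme)."""
        INF = float("inf")

        def post(node) -> tuple[float, float]:
            # (cost if node state 0, cost if node state 1)
            kids = self.children(node)
            if len(node) == 1 and not kids:
                (region,) = node
                return (INF, 0.0) if region in pattern else (0.0, INF)
            c0 = c1 = 0.0
            for k in kids:
                k0, k1 = post(k)
                c0 += min(k0, k1 + 1)
                c1 += min(k1, k0 + 1)
            return c0, c1

        c0, c1 = post(clade)
        return int(min(c0, c1 + 1))  # edge from the state-0 root


def _laminar_compatible(s: frozenset, family: list[frozenset]) -> bool:
    return all(s <= t or t <= s or not (s & t) for t in family)


def _assemble_tree(
    regions: list[str], family: list[frozenset], groups: dict
) -> PhyloTree:
    """Tree from a laminar family; non-family patterns become homoplasy."""
    full = frozenset(regions)
    edge_variants: dict[frozenset, list[int]] = {c: [] for c in family}
    homoplasy: list[tuple] = []
    for pattern, vids in sorted(
        groups.items(), key=lambda kv: (-len(kv[1]), tuple(sorted(kv[0])))
    ):
        if pattern in edge_variants:
            edge_variants[pattern].extend(vids)
            continue
        target = max(
            family,
            key=lambda t: (
                len(pattern & t) / len(pattern | t),
                -len(t),
                tuple(sorted(t)),
            ),
        )
        for v in vids:
            homoplasy.append((v, pattern, target))
            edge_variants[target].append(v)

    parent: dict[frozenset, frozenset | None] = {full: None}
    for clade in family:
        if clade == full:
            continue
        supersets = [t for t in family if clade < t]
        parent[clade] = min(supersets, key=lambda t: (len(t), tuple(sorted(t))))

    return PhyloTree(
        regions=regions,
        clades=sorted(family, key=lambda c: (-len(c), tuple(sorted(c)))),
        parent=parent,
        edge_variants=edge_variants,
        homoplasy=homoplasy,
    )


def build_tree(
    matrix: RegionCallMatrix,
    annotations: list[ClonalAnnotation],
    refine_max_conflicts: int = 12,
) -> PhyloTree:
    """Maximum-parsimony tree from presence patterns.

    Deduplicated patterns are processed in order of descending variant
    support (ties broken lexicographically on the sorted region tuple) and
    accepted when nested-or-disjoint with everything accepted so far.  The
    full region set (trunk) and all singletons are clades by construction,
    so the tree always has a trunk edge at the root and one leaf edge per
    region.  When conflicts arise, the small set of patterns involved is
    refined exhaustively: every laminar subset of the conflicted patterns
    is scored by total parsimony changes and the cheapest kept (greedy
    order alone can misjudge which side of a conflict to keep).  Variants
    of rejected patterns are assigned to the accepted clade with maximal
    Jaccard similarity and reported as homoplasy, never dropped.
    """
    if not annotations:
        raise ValueError("cannot build a tree from zero annotations")
    regions = list(matrix.regions)
    full = frozenset(regions)

    # trunk-classified variants map to the full clade even when a coverage
    # hole left a region indeterminate: classification is the authority on
    # trunk, and holes must not spawn spurious near-full branch patterns
    groups: dict[frozenset, list[int]] = {}
    for a in annotations:
        pattern = full if a.clonal_class == TRUNK else a.region_set
        groups.setdefault(pattern, []).append(a.variant_index)

    forced = [full] + [frozenset([r]) for r in regions]
    candidates = [p for p in groups if p not in forced]
    order = sorted(candidates, key=lambda p: (-len(groups[p]), tuple(sorted(p))))

    accepted: list[frozenset] = []
    rejected: list[frozenset] = []
    for pattern in order:
        if _laminar_compatible(pattern, forced + accepted):
            accepted.append(pattern)
        else:
            rejected.append(pattern)

    tree = _assemble_tree(regions, forced + accepted, groups)
    if not rejected:
        return tree

    # exhaustive refinement over the conflict set
    conflict = list(rejected) + [
        a for a in accepted
        if any(not (a <= r or r <= a or not (a & r)) for r in rejected)
    ]
    if len(conflict) > refine_max_conflicts:
        logger.info("conflict set too large (%d patterns); keeping greedy tree",
                    len(conflict))
        _log_homoplasy(tree)
        return tree

    fixed = forced + [a for a in accepted if a not in conflict]
    conflict = sorted(conflict, key=lambda p: (-len(groups[p]), tuple(sorted(p))))
    # helper clades: intersections of conflicting patterns carry no variants
    # themselves but can lower the Fitch cost of several patterns at once
    helper_set = set()
    for i, a in enumerate(conflict):
        for b in conflict[i + 1:]:
            for h in (a & b, a - b, b - a):
                if len(h) >= 2 and h != full and h not in groups:
                    helper_set.add(h)
    helpers = sorted(helper_set, key=lambda p: (-len(p), tuple(sorted(p))))
    conflict += helpers[: max(0, refine_max_conflicts - len(conflict))]
    best_tree, best_cost = tree, tree.parsimony_cost()
    for mask in range(1 << len(conflict)):
        subset = [conflict[k] for k in range(len(conflict)) if mask >> k & 1]
        if not all(_laminar_compatible(s, fixed + subset[:i])
                   for i, s in enumerate(subset)):
            continue
        cand = _assemble_tree(regions, fixed + subset, groups)
        cost = cand.parsimony_cost()
        if cost < best_cost:
            best_tree, best_cost = cand, cost
    _log_homoplasy(best_tree)
    return best_tree


def _log_homoplasy(tree: PhyloTree) -> None:
    by_pattern: dict[frozenset, int] = {}
    for _v, pattern, _t in tree.homoplasy:
        by_pattern[pattern] = by_pattern.get(pattern, 0) + 1
    for pattern, n in by_pattern.items():
        logger.info("pattern %s conflicts with the tree; %d variants carried "
                    "as homoplasy", sorted(pattern), n)


# ---------------------------------------------------------------------------
# PT vs IT heterogeneity enrichment


def heterogeneity_enrichment(
    annotations: list[ClonalAnnotation], region_kinds: dict[str, str]
) -> tuple[float, np.ndarray]:
    """Fisher test for enrichment of heterogeneous mutations in PT vs IT.

    Pools presence calls over regions of each kind into a 2x2 table
    (rows PT/IT, columns non-trunk/trunk presence calls) and applies the
    two-sided Fisher exact test.  Returns (p, table).
    """
    pt = {r for r, k in region_kinds.items() if k == "PT"}
    it = {r for r, k in region_kinds.items() if k == "IT"}
    if not pt or not it:
        raise ValueError("need at least one PT and one IT region")
    table = np.zeros((2, 2), dtype=np.int64)
    for a in annotations:
        row_nontrunk = 0 if a.clonal_class != TRUNK else 1
        table[0, row_nontrunk] += len(a.region_set & pt)
        table[1, row_nontrunk] += len(a.region_set & it)
    # columns: [non-trunk calls, trunk calls]
    table = table[:, ::-1]
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.warning("degenerate 2x2 table in heterogeneity enrichment: %s", table)
        return 1.0, table
    p = float(sps.fisher_exact(table, alternative="two-sided")[1])
    return p, table
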