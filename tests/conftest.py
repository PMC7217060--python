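import numpy as np
import pytest

from melith import clonality, regioncalls, simcase
from melith.variant_io import PresenceStatus, RegionCallMatrix, SomaticVariant


def pattern_matrix(regions, patterns, depth=100, alt_present=30):
    """Matrix whose rows realise given presence patterns, statuses set.

    ``patterns`` is a list of iterables of region ids (one per variant) or a
    dict pattern -> variant count.
    """
    if isinstance(patterns, dict):
        expanded = [s for s, w in patterns.items() for _ in range(w)]
    else:
        expanded = list(patterns)
    n, m = len(expanded), len(regions)
    d = np.full((n, m), depth, dtype=np.int64)
    a = np.zeros((n, m), dtype=np.int64)
    for i, s in enumerate(expanded):
        for j, r in enumerate(regions):
            if r in s:
                a[i, j] = alt_present
    status = np.where(a > 0, PresenceStatus.PRESENT, PresenceStatus.ABSENT).astype(np.int8)
    variants = [SomaticVariant("chr1", i + 1, "C", "T", "ACA") for i in range(n)]
    return RegionCallMatrix(variants, list(regions), d, a, status)


def run_pipeline(config):
    """simulate -> call -> purity-exclude -> drop empty rows -> classify."""
    matrix, bins, truth = simcase.simulate_case(config)
    called = regioncalls.call_presence(matrix)
    purities = regioncalls.estimate_purity(called)
    retained = regioncalls.drop_excluded(called, purities)
    retained = retained.subset_variants(np.flatnonzero(retained.present.any(axis=1)))
    annotations = clonality.classify(retained)
    return matrix, bins, truth, purities, retained, annotations


def parsimony_instance(rng):
    """Random clone-tree-style presence patterns with minority noise.

    Mirrors the structure multi-region data produces: a dominant trunk
    pattern, up to two nested branch clades, per-region privates, and 0-2
    single-variant conflicting (noise) patterns.
    """
    nreg = int(rng.integers(3, 6))
    regions = [f"R{i}" for i in range(nreg)]
    pats = {frozenset(regions): int(rng.integers(20, 60))}
    for _ in range(int(rng.integers(0, 3))):
        size = int(rng.integers(2, nreg))
        s = frozenset(rng.choice(regions, size=size, replace=False))
        if s not in pats and all(s <= t or t <= s or not (s & t) for t in pats):
            pats[s] = int(rng.integers(5, 20))
    for r in regions:
        if rng.random() < 0.8:
            pats[frozenset([r])] = pats.get(frozenset([r]), 0) + int(rng.integers(2, 7))
    for _ in range(int(rng.integers(0, 3))):
        size = int(rng.integers(2, nreg))
        s = frozenset(rng.choice(regions, size=size, replace=False))
        pats[s] = pats.get(s, 0) + 1
    return regions, pats


@pytest.fixture(scope="session")
def default_case():
    """One full default-condition case, shared across tests (seed 1)."""
    config = simcase.SimConfig(seed=1)
    matrix, bins, truth, purities, retained, annotations = run_pipeline(config)
    return {
        "config": config,
        "matrix": matrix,
        "bins": bins,
        "truth": truth,
        "purities": purities,
        "retained": retained,
        "annotations": annotations,
    }
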