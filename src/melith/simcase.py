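"""Synthetic multi-region tumor case and cohort generator with ground truth.

The case generator emulates a chronically sun-damaged melanoma with a
primary tumor sampled in several regions plus synchronous in-transit
metastases: a dominant trunk clone carrying ~96% of mutations, a small
laminar set of branch clones and per-region private clones, UV-dominated
substitution spectra that differ between trunk and non-trunk mutations,
CC>TT tandem substitutions, region-specific tumor purity (including
low-purity regions the pipeline should discard), and region-subset copy
number events including a focal deletion and an LOH that removes or
dilutes the mutations it covers.

Read counts follow the standard diploid-heterozygous model: the expected
alt-read fraction of a mutation in a region is

    p = purity x clone-fraction x m / 2

with m the effective allele multiplicity (1 on neutral territory; scaled
by CNA events — an LOH that removes the mutant allele in a fraction f of
tumor cells leaves m = 1 - f).  Depth is negative binomial around the
configured mean, alt counts binomial given depth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cnahet import CNASegment
from .variant_io import (
    RegionCallMatrix,
    SomaticVariant,
    write_multisample_vcf,
    write_sample_sheet,
    write_segments,
)

__all__ = ["CNAEvent", "SimConfig", "SimTruth", "simulate_case",
           "simulate_cohort", "write_case_outputs", "TOY_GENOME"]

# Toy genome: two large neutral chromosomes plus small analogues of the
# chromosomes carrying the focal deletion and the LOH event, sized so the
# LOH segment covers roughly the share of mutations seen in the case study.
TOY_GENOME: dict[str, int] = {
    "chr1": 65_000_000,
    "chr2": 65_000_000,
    "chr9": 5_000_000,
    "chr14": 5_000_000,
}

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CNAEvent:
    """A ground-truth copy-number event on a region subset.

    ``kind`` is gain, loss, or loh.  For loh, ``allele`` says which allele
    the event removes: ``mutant`` (mutations in the interval disappear in
    the affected regions) or ``wt`` (their VAF rises).  ``fraction`` is
    the proportion of tumor cells carrying the event (1.0 = clonal within
    the region; 0.5 models a 50/50 mixture of cells with and without it).
    """

    chrom: str
    start: int  # 0-based half-open
    end: int
    regions: tuple[str, ...]
    kind: str  # gain | loss | loh
    allele: str = "mutant"  # for loh
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("gain", "loss", "loh"):
            raise ValueError(f"unknown CNA kind {self.kind!r}")
        if self.allele not in ("mutant", "wt"):
            raise ValueError(f"unknown allele flag {self.allele!r}")
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError("event fraction must be in (0, 1]")
        if self.end <= self.start:
            raise ValueError("empty CNA interval")

    @property
    def tumor_copy_number(self) -> float:
        base = {"gain": 3.0, "loss": 1.0, "loh": 1.0}[self.kind]
        return self.fraction * base + (1 - self.fraction) * 2.0


def _default_region_ids(n_regions: int) -> list[str]:
    if n_regions == 12:
        return [f"PT{i}" for i in range(1, 6)] + [f"IT{i}" for i in range(1, 8)]
    n_pt = max(1, round(n_regions * 5 / 12))
    return [f"PT{i}" for i in range(1, n_pt + 1)] + [
        f"IT{i}" for i in range(1, n_regions - n_pt + 1)
    ]


def _default_purities(region_ids: list[str]) -> list[float]:
    # PT1 and IT6 analogues are the low-purity specimens the pipeline must drop
    low = {"PT1", "IT6"}
    return [0.15 if r in low else 0.6 for r in region_ids]


def _default_cna_events() -> list[CNAEvent]:
    return [
        # shared single-copy gain on chr2 (stands for the ubiquitous gains)
        CNAEvent("chr2", 0, 20_000_000,
                 tuple(_default_region_ids(12)), "gain"),
        # focal deletion on chr9 (CDKN2A analogue) in three IT regions only
        CNAEvent("chr9", 2_000_000, 3_000_000, ("IT1", "IT3", "IT7"), "loss"),
        # clonal mutant-allele LOH on chr14 in PT4: covered mutations vanish
        CNAEvent("chr14", 0, 1_000_000, ("PT4",), "loh", allele="mutant",
                 fraction=1.0),
        # the same interval under a 50/50 subclonal LOH in IT2: VAF halves
        CNAEvent("chr14", 0, 1_000_000, ("IT2",), "loh", allele="mutant",
                 fraction=0.5),
    ]


@dataclass
class SimConfig:
    """Study conditions for the multi-region case simulation.

    Defaults mirror the analysed case: 12 regions (5 PT + 7 IT) of which
    two are low purity, 1,844 somatic mutations with 96.2% on the trunk,
    80% / 57% UV-attributable substitutions among trunk / non-trunk
    events, 9% of SNVs forming adjacent-position DNVs of which 87% are
    CC>TT, ~100x mean depth, and the chr9/chr14 copy-number scenarios.
    """

    seed: int
    n_regions: int = 12
    n_mutations: int = 1844
    trunk_fraction: float = 0.962
    p_uv_trunk: float = 0.80
    p_uv_nontrunk: float = 0.57
    dnv_rate: float = 0.09  # DNV events per SNV
    cc_tt_fraction: float = 0.87
    purity_per_region: list[float] | None = None
    mean_depth: float = 100.0
    depth_dispersion: float = 0.1
    n_insertions: int = 7
    n_deletions: int = 18
    cna_events: list[CNAEvent] | None = None
    region_ids: list[str] | None = None
    branch_patterns: list[tuple[tuple[str, ...], float]] | None = None
    branch_ccf: float = 0.6
    private_ccf: float = 0.4
    min_purity_retained: float = 0.2
    bin_size: int = 25_000
    bin_noise_sd: float = 0.12
    genome: dict[str, int] = field(default_factory=lambda: dict(TOY_GENOME))

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for any stochastic call")
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        for name in ("trunk_fraction", "p_uv_trunk", "p_uv_nontrunk", "dnv_rate",
                     "cc_tt_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.region_ids is None:
            self.region_ids = _default_region_ids(self.n_regions)
        if len(self.region_ids) != self.n_regions:
            raise ValueError("region_ids length must equal n_regions")
        if self.purity_per_region is None:
            self.purity_per_region = _default_purities(self.region_ids)
        if len(self.purity_per_region) != self.n_regions:
            raise ValueError("purity list length must equal n_regions")
        if any(not (0.0 <= p <= 1.0) for p in self.purity_per_region):
            raise ValueError("purities must be in [0, 1]")
        if round(self.trunk_fraction * self.n_mutations) < 1:
            raise ValueError("trunk_fraction x n_mutations must be at least 1")
        if self.n_insertions + self.n_deletions >= self.n_mutations:
            raise ValueError("indel counts exceed the mutation budget")
        if self.cna_events is None:
            self.cna_events = [
                e for e in _default_cna_events()
                if set(e.regions) & set(self.region_ids)
            ]
            self.cna_events = [
                dataclasses.replace(
                    e, regions=tuple(r for r in e.regions if r in self.region_ids)
                )
                for e in self.cna_events
            ]
        self._check_event_overlap()
        if self.branch_patterns is None:
            default = tuple(
                r for r in ("PT3", "PT5", "IT3", "IT4") if r in self.region_ids
            )
            self.branch_patterns = [(default, 0.25)] if len(default) >= 2 else []

    def _check_event_overlap(self) -> None:
        for i, a in enumerate(self.cna_events):
            for b in self.cna_events[i + 1:]:
                if (
                    a.chrom == b.chrom
                    and set(a.regions) & set(b.regions)
                    and a.start < b.end
                    and b.start < a.end
                ):
                    raise ValueError(
                        f"overlapping CNA events on the same region: {a} / {b}"
                    )

    @property
    def region_kinds(self) -> dict[str, str]:
        return {r: ("PT" if r.startswith("PT") else "IT") for r in self.region_ids}

    @property
    def retained_regions(self) -> list[str]:
        return [
            r for r, p in zip(self.region_ids, self.purity_per_region)
            if p >= self.min_purity_retained
        ]

    def to_yaml(self, path: str | Path) -> None:
        def listify(o):
            if isinstance(o, (list, tuple)):
                return [listify(x) for x in o]
            if isinstance(o, dict):
                return {k: listify(v) for k, v in o.items()}
            return o

        d = dataclasses.asdict(self)
        d["cna_events"] = [dataclasses.asdict(e) for e in self.cna_events]
        with open(path, "w") as fh:
            yaml.safe_dump(listify(d), fh, sort_keys=False)


@dataclass
class SimTruth:
    """Generating ground truth for parameter-recovery tests.

    ``region_clone_mix`` gives, per region, the disjoint cell-population
    mixture over tumor clones (proportions sum to the tumor fraction of 1;
    the remainder of the specimen is normal tissue via purity).  Mutations
    erased by a clonal LOH ride the trunk population — their own clone id
    appears in ``clone_tree`` only to book-keep the allelic loss.
    ``expected_vaf`` is the variants x regions grid of expected alt-read
    fractions the read sampler used.
    """

    clone_tree: dict  # clone id -> parent clone id ("normal" is the root)
    mutation_clone: list  # per-variant clone id
    mutation_class: list  # per-variant trunk|branch|private by construction
    region_clone_mix: dict  # region -> {clone: disjoint cell fraction}
    cna_truth: list  # ground-truth CNASegment records (aberrant intervals)
    region_excluded_expected: list
    mutations: pd.DataFrame = None  # per-variant truth table
    dnv_pairs: list = field(default_factory=list)  # (index_a, index_b)
    expected_vaf: np.ndarray | None = None

    def __post_init__(self) -> None:
        for clone in set(self.mutation_clone):
            if clone not in self.clone_tree:
                raise ValueError(f"mutation assigned to unknown clone {clone}")


# ---------------------------------------------------------------------------
# case simulation


def _events_covering(config: SimConfig, chrom: str, pos0: int) -> list[CNAEvent]:
    return [
        e for e in config.cna_events
        if e.chrom == chrom and e.start <= pos0 < e.end
    ]


def _forbidden_intervals(config: SimConfig) -> list[tuple[str, int, int]]:
    """Intervals where trunk/branch/private mutations must not land: clonal
    mutant-lost LOH territory (its mutations are generated separately so the
    configured class fractions stay exact)."""
    return [
        (e.chrom, e.start, e.end)
        for e in config.cna_events
        if e.kind == "loh" and e.allele == "mutant" and e.fraction >= 1.0
    ]


def _draw_position(rng, config: SimConfig, forbidden, interval=None) -> tuple[str, int]:
    chroms = list(config.genome)
    sizes = np.array([config.genome[c] for c in chroms], dtype=float)
    while True:
        if interval is not None:
            chrom = interval[0]
            pos0 = int(rng.integers(interval[1], interval[2]))
        else:
            chrom = chroms[rng.choice(len(chroms), p=sizes / sizes.sum())]
            pos0 = int(rng.integers(0, config.genome[chrom]))
        if interval is None and any(
            c == chrom and s <= pos0 < e for c, s, e in forbidden
        ):
            continue
        return chrom, pos0


def _snv_alleles(rng, uv: bool) -> tuple[str, str, str]:
    """(ref, alt, tri_context) on the pyrimidine strand."""
    if uv:
        five = _BASES[rng.choice([1, 3])]  # C or T: dipyrimidine 5' context
        three = _BASES[rng.integers(0, 4)]
        return "C", "T", f"{five}C{three}"
    kind = int(rng.integers(0, 6))
    if kind < 5:
        ref, alt = [("C", "A"), ("C", "G"), ("T", "A"), ("T", "C"), ("T", "G")][kind]
        five = _BASES[rng.integers(0, 4)]
        three = _BASES[rng.integers(0, 4)]
        return ref, alt, f"{five}{ref}{three}"
    # C>T with purine 5' context: not UV-attributable
    five = _BASES[rng.choice([0, 2])]  # A or G
    three = _BASES[rng.integers(0, 4)]
    return "C", "T", f"{five}C{three}"


_NON_CCTT_DNVS = [("CT", "TA"), ("TC", "CT"), ("CA", "AC"), ("TG", "GT")]


def simulate_case(config: SimConfig):
    """Simulate one multi-region case.

    Returns ``(matrix, bins, truth)``: an uncalled RegionCallMatrix, a
    per-region binned log2-ratio frame for segmentation, and the SimTruth.
    Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    regions = list(config.region_ids)
    purity = dict(zip(regions, config.purity_per_region))
    retained = config.retained_regions
    if len(retained) < 2:
        raise ValueError("fewer than 2 regions above the purity threshold")

    n = config.n_mutations
    n_trunk = int(round(config.trunk_fraction * n))
    n_nontrunk = n - n_trunk

    # --- clone structure -------------------------------------------------
    clone_tree: dict[str, str] = {"trunk": "normal"}
    clone_regions: dict[str, tuple[str, ...]] = {"trunk": tuple(regions)}
    clone_ccf: dict[str, float] = {"trunk": 1.0}
    clone_class: dict[str, str] = {"trunk": "trunk"}

    # mutations erased by a clonal mutant-lost LOH behave as branch
    # mutations (present everywhere except the affected regions); they are
    # drawn from the non-trunk budget and placed inside the LOH interval
    shadow_quota: dict[str, tuple[CNAEvent, int]] = {}
    budget = n_nontrunk
    genome_len = sum(config.genome.values())
    for e in config.cna_events:
        if e.kind == "loh" and e.allele == "mutant" and e.fraction >= 1.0:
            quota = min(budget, int(round(n * (e.end - e.start) / genome_len)))
            if quota == 0:
                continue
            cid = f"loh_shadow_{e.chrom}_{'_'.join(e.regions)}"
            clone_tree[cid] = "trunk"
            clone_regions[cid] = tuple(r for r in regions if r not in e.regions)
            clone_ccf[cid] = 1.0
            clone_class[cid] = "branch"
            shadow_quota[cid] = (e, quota)
            budget -= quota

    branch_quota: dict[str, int] = {}
    for k, (pattern, share) in enumerate(config.branch_patterns):
        quota = min(budget, int(round(share * n_nontrunk)))
        if quota == 0 or len(pattern) < 2:
            continue
        cid = f"branch_{k}"
        clone_tree[cid] = "trunk"
        clone_regions[cid] = tuple(pattern)
        clone_ccf[cid] = config.branch_ccf
        clone_class[cid] = "branch"
        branch_quota[cid] = quota
        budget -= quota

    private_regions = retained
    for r in private_regions:
        cid = f"private_{r}"
        parent = "trunk"
        for bc in branch_quota:  # nest under a branch clone when inside it
            if r in clone_regions[bc]:
                parent = bc
        clone_tree[cid] = parent
        clone_regions[cid] = (r,)
        clone_ccf[cid] = config.private_ccf
        clone_class[cid] = "private"

    # --- per-variant clone assignment ------------------------------------
    mutation_clone: list[str] = ["trunk"] * n_trunk
    for cid, (e, quota) in shadow_quota.items():
        mutation_clone += [cid] * quota
    for cid, quota in branch_quota.items():
        mutation_clone += [cid] * quota
    leftovers = n - len(mutation_clone)
    for i in range(leftovers):
        mutation_clone.append(f"private_{private_regions[i % len(private_regions)]}")
    mutation_clone = list(rng.permutation(mutation_clone))
    mutation_class = [clone_class[c] for c in mutation_clone]

    # --- indels and DNV pairing ------------------------------------------
    idx_all = np.arange(n)
    indel_idx = rng.choice(idx_all, size=config.n_insertions + config.n_deletions,
                           replace=False)
    ins_idx = set(int(i) for i in indel_idx[: config.n_insertions])
    del_idx = set(int(i) for i in indel_idx[config.n_insertions:])
    snv_idx = [i for i in range(n) if i not in ins_idx and i not in del_idx]
    n_snv = len(snv_idx)
    n_dnv = int(round(config.dnv_rate * n_snv))

    # pair SNVs of the same clone into DNV events
    by_clone: dict[str, list[int]] = {}
    for i in snv_idx:
        by_clone.setdefault(mutation_clone[i], []).append(i)
    clone_order = sorted(by_clone, key=lambda c: (-len(by_clone[c]), c))
    shuffled = {c: list(rng.permutation(by_clone[c])) for c in clone_order}
    dnv_pairs: list[tuple[int, int]] = []
    # proportional allocation per clone, then a top-up pass so the realised
    # event count matches round(dnv_rate x n_snv) whenever members allow
    for cid in clone_order:
        members = shuffled[cid]
        want = min(int(n_dnv * len(members) / n_snv), len(members) // 2,
                   n_dnv - len(dnv_pairs))
        for _ in range(want):
            a, b = members.pop(), members.pop()
            dnv_pairs.append((int(a), int(b)))
    for cid in clone_order:
        members = shuffled[cid]
        while len(dnv_pairs) < n_dnv and len(members) >= 2:
            a, b = members.pop(), members.pop()
            dnv_pairs.append((int(a), int(b)))
    dnv_member: dict[int, int] = {}
    for a, b in dnv_pairs:
        dnv_member[a] = b
        dnv_member[b] = a

    # --- UV assignment per unit (standalone SNV or DNV event) -------------
    # The SNV-level UV probability is adjusted so that the class-level UV
    # fraction over units (SNVs + DNV events, CC>TT counting as UV) matches
    # the configured p_uv even though the CC>TT share of DNVs is its own
    # parameter.
    is_uv: dict[int, bool] = {}
    dnv_is_cctt: dict[tuple[int, int], bool] = {}
    for class_label, p_uv in (("trunk", config.p_uv_trunk),
                              ("nontrunk", config.p_uv_nontrunk)):
        if class_label == "trunk":
            members = [i for i in snv_idx if mutation_class[i] == "trunk"]
        else:
            members = [i for i in snv_idx if mutation_class[i] != "trunk"]
        member_set = set(members)
        pairs = [pq for pq in dnv_pairs if pq[0] in member_set]
        standalone = [i for i in members if i not in dnv_member]
        n_units = len(standalone) + len(pairs)
        if n_units == 0:
            continue
        for pq in pairs:
            dnv_is_cctt[pq] = bool(rng.random() < config.cc_tt_fraction)
        exp_uv_dnv = config.cc_tt_fraction * len(pairs)
        p_snv_uv = 0.0
        if standalone:
            p_snv_uv = float(
                np.clip((p_uv * n_units - exp_uv_dnv) / len(standalone), 0.0, 1.0)
            )
        for i in standalone:
            is_uv[i] = bool(rng.random() < p_snv_uv)

    # --- positions and alleles --------------------------------------------
    forbidden = _forbidden_intervals(config)
    variants: list[SomaticVariant | None] = [None] * n
    chrom_of: list[str] = [""] * n
    pos_of: list[int] = [0] * n
    occupied: set[tuple[str, int]] = set()

    def place(clone: str, width: int = 1) -> tuple[str, int]:
        interval = None
        if clone in shadow_quota:
            e = shadow_quota[clone][0]
            interval = (e.chrom, e.start, e.end - width)
        while True:
            chrom, pos0 = _draw_position(rng, config, forbidden, interval)
            span = {(chrom, pos0 + k) for k in range(-1, width + 1)}
            if not (span & occupied):
                occupied.update((chrom, pos0 + k) for k in range(width))
                return chrom, pos0

    # DNV events first (they need two adjacent free positions)
    for (a, b) in dnv_pairs:
        chrom, pos0 = place(mutation_clone[a], width=2)
        cctt = dnv_is_cctt[(a, b)]
        if cctt:
            five = _BASES[int(rng.integers(0, 4))]
            three = _BASES[int(rng.integers(0, 4))]
            ref_d, alt_d = "CC", "TT"
            ctx_a, ctx_b = f"{five}CC", f"CC{three}"
        else:
            ref_d, alt_d = _NON_CCTT_DNVS[int(rng.integers(0, len(_NON_CCTT_DNVS)))]
            five = _BASES[int(rng.integers(0, 4))]
            three = _BASES[int(rng.integers(0, 4))]
            ctx_a = f"{five}{ref_d[0]}{ref_d[1]}"
            ctx_b = f"{ref_d[0]}{ref_d[1]}{three}"
        if rng.random() < 0.5:  # present the event on the opposite strand
            ref_d, alt_d = _revcomp(ref_d), _revcomp(alt_d)
            ctx_a, ctx_b = _revcomp(ctx_b), _revcomp(ctx_a)
        variants[a] = SomaticVariant(chrom, pos0 + 1, ref_d[0], alt_d[0], ctx_a)
        variants[b] = SomaticVariant(chrom, pos0 + 2, ref_d[1], alt_d[1], ctx_b)
        chrom_of[a], pos_of[a] = chrom, pos0
        chrom_of[b], pos_of[b] = chrom, pos0 + 1

    for i in range(n):
        if variants[i] is not None:
            continue
        clone = mutation_clone[i]
        if i in ins_idx or i in del_idx:
            chrom, pos0 = place(clone, width=2)
            base = _BASES[int(rng.integers(0, 4))]
            other = _BASES[int(rng.integers(0, 4))]
            if i in ins_idx:
                variants[i] = SomaticVariant(chrom, pos0 + 1, base, base + other)
            else:
                variants[i] = SomaticVariant(chrom, pos0 + 1, base + other, base)
        else:
            chrom, pos0 = place(clone, width=1)
            ref, alt, ctx = _snv_alleles(rng, is_uv.get(i, False))
            if rng.random() < 0.5:
                ref, alt, ctx = _revcomp(ref), _revcomp(alt), _revcomp(ctx)
            variants[i] = SomaticVariant(chrom, pos0 + 1, ref, alt, ctx)
        chrom_of[i], pos_of[i] = chrom, pos0

    # --- read counts -------------------------------------------------------
    depth = np.zeros((n, len(regions)), dtype=np.int64)
    alt = np.zeros((n, len(regions)), dtype=np.int64)
    r_param = 1.0 / config.depth_dispersion
    p_nb = r_param / (r_param + config.mean_depth)
    expected_p = np.zeros((n, len(regions)))

    for j, region in enumerate(regions):
        pur = purity[region]
        for i in range(n):
            clone = mutation_clone[i]
            if region not in clone_regions[clone]:
                continue
            m_eff = 1.0
            for e in _events_covering(config, chrom_of[i], pos_of[i]):
                if region not in e.regions:
                    continue
                if e.kind == "loh":
                    if e.allele == "mutant":
                        m_eff *= max(0.0, 1.0 - e.fraction)
                    else:
                        m_eff *= 1.0 + e.fraction
                elif e.kind == "loss":
                    # hemizygous deletion retaining the mutated homolog
                    m_eff *= 2.0 / (2.0 - e.fraction * pur)
            expected_p[i, j] = min(0.999, pur * clone_ccf[clone] * m_eff / 2.0)
    depth[:, :] = rng.negative_binomial(r_param, p_nb, size=(n, len(regions)))
    alt[:, :] = rng.binomial(depth, expected_p)

    matrix = RegionCallMatrix(variants, regions, depth, alt)

    # --- copy-number bins --------------------------------------------------
    bins = _simulate_bins(rng, config, purity)

    cna_truth = []
    for e in config.cna_events:
        for r in e.regions:
            pur = purity[r]
            cn = e.tumor_copy_number
            log2 = float(np.log2((2 * (1 - pur) + cn * pur) / 2.0))
            cna_truth.append(
                CNASegment(
                    region_id=r, chrom=e.chrom, start=e.start, end=e.end,
                    n_bins=max(1, (e.end - e.start) // config.bin_size),
                    log2_ratio=log2,
                    call="gain" if e.kind == "gain" else "loss",
                )
            )

    # disjoint cell-population mixture per region: private inside branch
    # (when nested) inside trunk; LOH-shadow clones are trunk cells
    region_clone_mix: dict[str, dict[str, float]] = {}
    for r in regions:
        mix: dict[str, float] = {}
        branch_here = [
            c for c in branch_quota if r in clone_regions[c]
        ]
        private_here = f"private_{r}" if f"private_{r}" in clone_tree else None
        p_priv = clone_ccf[private_here] if private_here else 0.0
        used = 0.0
        if private_here:
            mix[private_here] = p_priv
            used += p_priv
        for c in branch_here:
            share = max(0.0, clone_ccf[c] - used)
            if share > 0:
                mix[c] = share
                used = clone_ccf[c]
        mix["trunk"] = max(0.0, 1.0 - used)
        region_clone_mix[r] = mix

    truth_df = pd.DataFrame(
        {
            "chrom": [v.chrom for v in variants],
            "pos": [v.pos for v in variants],
            "ref": [v.ref for v in variants],
            "alt": [v.alt for v in variants],
            "clone": mutation_clone,
            "clonal_class": mutation_class,
            "is_indel": [not v.is_snv for v in variants],
            "is_dnv_member": [i in dnv_member for i in range(n)],
            "is_uv_unit": [
                bool(
                    dnv_is_cctt.get((i, dnv_member[i]), dnv_is_cctt.get((dnv_member[i], i)))
                )
                if i in dnv_member
                else is_uv.get(i, False)
                for i in range(n)
            ],
        }
    )

    truth = SimTruth(
        clone_tree=clone_tree,
        mutation_clone=mutation_clone,
        mutation_class=mutation_class,
        region_clone_mix=region_clone_mix,
        cna_truth=cna_truth,
        region_excluded_expected=[
            r for r in regions if purity[r] < config.min_purity_retained
        ],
        mutations=truth_df,
        dnv_pairs=dnv_pairs,
        expected_vaf=expected_p,
    )
    return matrix, bins, truth


def _simulate_bins(rng, config: SimConfig, purity: dict[str, float]) -> pd.DataFrame:
    frames = []
    for region in config.region_ids:
        pur = purity[region]
        for chrom, size in config.genome.items():
            starts = np.arange(0, size, config.bin_size, dtype=np.int64)
            ends = np.minimum(starts + config.bin_size, size)
            mids = (starts + ends) // 2
            base = np.zeros(starts.size)
            for e in config.cna_events:
                if e.chrom != chrom or region not in e.regions:
                    continue
                cn = e.tumor_copy_number
                log2 = np.log2((2 * (1 - pur) + cn * pur) / 2.0)
                mask = (mids >= e.start) & (mids < e.end)
                base[mask] = log2
            noise = rng.normal(0.0, config.bin_noise_sd, size=starts.size)
            frames.append(
                pd.DataFrame(
                    {
                        "region_id": region,
                        "chrom": chrom,
                        "start": starts,
                        "end": ends,
                        "log2": base + noise,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def write_case_outputs(matrix, bins, truth, config: SimConfig, outdir: str | Path):
    """Write VCF, bin TSV, truth SEG, sample sheet, truth table and config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_multisample_vcf(matrix, outdir / "case.vcf")
    bins.to_csv(outdir / "cna_bins.tsv", sep="\t", index=False)
    write_segments(truth.cna_truth, outdir / "cna_truth.seg")
    sheet = pd.DataFrame(
        {
            "region_id": config.region_ids,
            "kind": [config.region_kinds[r] for r in config.region_ids],
            "purity": config.purity_per_region,
        }
    )
    write_sample_sheet(sheet, outdir / "sample_sheet.tsv")
    truth.mutations.to_csv(outdir / "mutation_truth.tsv", sep="\t", index=False)
    config.to_yaml(outdir / "sim_config.yaml")


# ---------------------------------------------------------------------------
# cohort simulation

DEFAULT_GENE_PROBS = {
    "BRAF": {"CSD_high": 0.39, "CSD_low": 0.53},
    "NF1": {"CSD_high": 0.35, "CSD_low": 0.08},
    "TP53": {"CSD_high": 0.48, "CSD_low": 0.12},
    "NRAS": {"CSD_high": 0.17, "CSD_low": 0.18},
}

# hotspot composition among BRAF-mutant samples; V600K enriched with
# chronic sun damage
DEFAULT_HOTSPOT_PROBS = {
    "BRAF": {
        "CSD_high": {"V600E": 0.30, "V600K": 0.50, "K601E": 0.20},
        "CSD_low": {"V600E": 0.70, "V600K": 0.10, "K601E": 0.20},
    }
}

DEFAULT_LOAD_PARAMS = {"CSD_high": (40.0, 0.25), "CSD_low": (18.0, 0.25)}


def simulate_cohort(
    n_high: int,
    n_low: int,
    gene_probs: dict | None = None,
    load_params: dict | None = None,
    seed: int | None = None,
    hotspot_probs: dict | None = None,
) -> pd.DataFrame:
    """Simulate a cohort mutation table.

    ``gene_probs`` maps gene -> {group: mutation probability};
    ``load_params`` maps group -> (mean, dispersion) of the negative
    binomial mutational-load distribution; ``hotspot_probs`` optionally
    maps gene -> group -> {protein change: probability} for mutant
    samples.  One row per sample x mutated gene; samples without hits keep
    a metadata row with an empty gene.  Deterministic given the seed.
    """
    if seed is None:
        raise ValueError("a seed is mandatory for any stochastic call")
    if n_high < 0 or n_low < 0:
        raise ValueError("negative sample counts rejected")
    gene_probs = DEFAULT_GENE_PROBS if gene_probs is None else gene_probs
    load_params = DEFAULT_LOAD_PARAMS if load_params is None else load_params
    hotspot_probs = DEFAULT_HOTSPOT_PROBS if hotspot_probs is None else hotspot_probs
    for gene, d in gene_probs.items():
        for g, p in d.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability out of range for {gene}/{g}: {p}")
    for g, (mean, disp) in load_params.items():
        if mean < 0 or disp <= 0:
            raise ValueError(f"invalid load parameters for {g}")

    rng = np.random.default_rng(seed)
    rows = []
    sample_no = 0
    for group, count in (("CSD_high", n_high), ("CSD_low", n_low)):
        mean, disp = load_params[group]
        r = 1.0 / disp
        p_nb = r / (r + mean) if mean > 0 else 1.0
        for k in range(count):
            sample_no += 1
            sid = f"S{sample_no:03d}"
            stage = "in_situ" if k % 2 == 0 else "invasive"
            load = int(rng.negative_binomial(r, p_nb)) if mean > 0 else 0
            hits = []
            for gene in sorted(gene_probs):
                if rng.random() < gene_probs[gene].get(group, 0.0):
                    pchange = ""
                    spots = hotspot_probs.get(gene, {}).get(group)
                    if spots:
                        labels = sorted(spots)
                        probs = np.array([spots[l] for l in labels], dtype=float)
                        probs = probs / probs.sum()
                        pchange = labels[int(rng.choice(len(labels), p=probs))]
                    hits.append((gene, pchange))
            if hits:
                for gene, pchange in hits:
                    rows.append((sid, group, stage, gene, pchange, load))
            else:
                rows.append((sid, group, stage, "", "", load))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "group", "stage", "gene", "protein_change",
                 "mutational_load"],
    )
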