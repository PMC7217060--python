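# Methods

## Presence calling and the rescue rule

Each (variant, region) cell is judged from its read counts alone. A cell
needs `min_depth_evaluable` (default 30) reads to be judged at all;
below that it is *indeterminate*, a state that is deliberately neither
present nor absent. A mutation is established *de novo* in a region with
`min_alt_denovo` (3) alternate reads at `min_vaf_denovo` (2%) VAF; once
established anywhere, `min_alt_rescue` (2) alternate reads suffice to accept
it elsewhere. The asymmetry encodes the working hypothesis of multi-region
calling: false heterogeneity (a clonal mutation missed in one region) is the
expensive error, so confirmation is cheaper than discovery. The defaults are
conservative for 70–130× exome coverage and are all configurable; raising
`min_alt_denovo` can only shrink the present set (a property the test suite
checks), and a variant de novo nowhere is never rescued.

Indeterminate cells are excluded from every downstream denominator: a trunk
mutation is one present in all *evaluable* regions (at least two), and DNV
merging ignores cells where either member is indeterminate. Coverage holes
therefore cannot masquerade as biology.

## Purity estimation and specimen exclusion

Before classification exists, variants present in ≥90% of regions serve as
trunk proxies. Under the heterozygous-diploid assumption a clonal mutation
sits on one of two copies in every tumor cell, so

    purity = min(1, 2 × median VAF of trunk proxies on copy-neutral territory).

The median is robust to the minority of sites where the diploid assumption
fails. Regions below `min_purity` (0.2) are excluded; with fewer than 10
supporting variants the estimate is flagged, not refused. Exclusion can
strand variants observed nowhere else; these are dropped and logged. The
real per-specimen purities behind the study's exclusions are not published;
the generator's defaults (0.6 retained, 0.15 excluded) are asserted values
chosen so that excluded specimens sit clearly below the floor and retained
ones clearly above it.

## Classification and the parsimony tree

Classes: trunk = present in all evaluable regions (≥2); private = present in
exactly one region; branch = everything else. Percentages are rounded
half-away-from-zero, the convention of the printed literature values.

The phylogeny treats each deduplicated presence pattern as a candidate clade.
A set of patterns that is pairwise nested-or-disjoint (a laminar family) is
exactly the clade set of one rooted tree, so the builder accepts patterns in
order of descending variant support (ties broken lexicographically) while
laminarity holds. The full region set and all singletons are clades by
construction: the tree always has a trunk edge at the root (root = normal
tissue, all characters absent) and one leaf edge per region. Branch length =
number of variants assigned to the edge.

Pure greedy acceptance can misjudge which side of a conflict to keep, so the
(typically tiny) set of patterns involved in conflicts is refined
exhaustively: every laminar subset of the conflicted patterns — augmented
with intersection and difference *helper clades*, which carry no variants but
can reduce the Fitch cost of several conflicting patterns at once — is scored
by total parsimony changes and the cheapest tree kept (cap: 12 conflicted
patterns, beyond which the greedy tree stands). Costs are computed with the
exact two-state small-parsimony dynamic programme, which is valid on
polytomies; since any multifurcating tree is an edge-contraction of a binary
one, the reported cost can never undercut the true binary-tree minimum. On
random clone-tree-like instances with minority noise the builder matches
exhaustive search over all trees in ≳97% of cases (verified against
`melith.reference.min_parsimony_cost` in the tests). Conflicting variants are
attached to the accepted clade with maximal Jaccard similarity and reported
as homoplasy, never dropped. The "shorten the trunk for display" convention
is an argument of the Newick renderer and never touches the data.

PT-vs-IT heterogeneity enrichment pools presence calls per specimen kind into
one 2×2 table (non-trunk vs trunk calls) and applies the two-sided Fisher
exact test; a degenerate margin returns p = 1 with a warning.

## Substitution spectra and UV attribution

Substitutions are reduced to the pyrimidine strand. Categories: C>A, C>G,
T>A, T>C, T>G, and C>T split four ways by 5′ purine (R) / pyrimidine (Y) ×
3′ G / non-G. Contexts containing N are counted apart as unclassifiable.
Indels never enter spectra.

Adjacent-position SNV pairs with identical (evaluable-cell) presence patterns
and per-region VAFs within a factor of 2 merge into DNV events; runs of ≥3
merge pairwise left to right with a warning. GG>AA is CC>TT on the other
strand. Members are flagged so nothing is double-counted: the partition
`SNV categories + unclassifiable + 2 × DNV events = total SNVs` is a tested
invariant.

**UV-attributable** means C>T with a 5′ pyrimidine (the two YC>T groups) —
the defining specificity of UV photoproducts, which form at dipyrimidine
sites — plus CC>TT DNV events. The fraction divides by all classified events
(SNVs plus DNV events, each DNV once). The literature this mirrors does not
state its operational attribution rule; this definition is the natural
context-based one and is isolated in `uv_fraction` so an alternative (e.g.
signature refitting, which is out of scope) could replace it. An empty
spectrum raises rather than returning 0: "no data" must not read as "no UV".

Spectrum comparisons: UV vs non-UV is the exact two-sided 2×2 Fisher test.
The full 2×k comparison samples tables from the fixed-margin null
(multivariate hypergeometric), orders them by Fisher's probability
criterion, and reports the add-one-smoothed tail fraction; 100,000
permutations and the seed are arguments. The exact 2×k network algorithm is
out of scope.

## Copy number and VAF reconciliation

Binned log2 tumor/normal ratios are segmented by recursive binary splitting:
the split maximising |Welch *t*| between flank means is accepted while
|t| ≥ 5 and both sides keep ≥ 10 bins; segment mean = bin mean; segments tile
each chromosome exactly, and raising the threshold can only merge. The
method is asserted (the upstream study names none) and both knobs are
exposed. Calls: log2 ≥ +0.2 gain, ≤ −0.2 loss — sized for single-copy events
at ~50% purity. Loci of interest (BED, 0-based half-open) are compared
across regions via the maximally overlapping segment; an aberration carried
by a proper nonempty subset of regions is heterogeneous.

`reconcile_vaf` asks why a chromosome's branch mutations are branch in a
given region. With ≥3 branch and ≥3 trunk mutations on the chromosome:
if ≥80% of the branch mutations are absent there → `loh_removed` (the
deletion took the mutant allele); else if present but significantly lower
than the trunk VAFs (two-sided rank-sum, p < 0.05, lower median) →
`subclonal_mixture`; else `concordant`. Whether the original analysis used a
formal test here is unstated; the rank-sum wrapper is this package's
formalisation.

## Statistical machinery

2×2 Fisher tests and the rank-sum test delegate to scipy behind the module
interfaces. The rank-sum test is exact (scipy's null distribution) whenever
there are no ties and the combined n ≤ 30 or both groups ≤ 25; with ties it
enumerates all group assignments with mid-ranks when C(n, n₁) ≤ 2×10⁵,
otherwise it uses the normal approximation with tie and continuity
corrections. Group-load comparisons are *unpaired*: the strata are
independent samples, so the rank-sum (Mann-Whitney) test is the correct
choice even where the source literature says "signed-rank" (a paired test).
No multiple-testing correction is applied by default (raw p-values are what
the literature prints); `benjamini_hochberg` exists for users who want it.

`melith.reference` holds deliberately slow, transparent oracles — full
hypergeometric enumeration, complete permutation, exhaustive tree search —
used only to validate the fast paths in the tests and acceptance script.

## The synthetic-data generator

`simulate_case` emulates a chronically sun-damaged melanoma sampled in 12
regions (5 PT + 7 IT, two of them low purity) on a four-chromosome toy
genome (65 + 65 + 5 + 5 Mb): two neutral chromosomes plus small analogues of
the chromosomes carrying the focal deletion and the LOH event, sized so the
1-Mb LOH interval covers ≈0.7% of mutations (the scale of the case study's
chr14 observation).

Defaults are the study conditions: 1,844 mutations (7 insertions, 18
deletions, the rest SNVs), trunk fraction 0.962, UV-unit probability 0.80
(trunk) / 0.57 (non-trunk), DNV rate 0.09 events per SNV with CC>TT fraction
0.87, purity 0.6 (retained) / 0.15 (excluded), mean depth 100 with negative
binomial dispersion 0.1 (overdispersion typical of exome capture; the
source reports only median coverage 68–126×).

Clone structure: one trunk clone (cancer-cell fraction 1 everywhere); one
branch clone over {PT3, PT5, IT3, IT4} at CCF 0.6 (the four-region pattern
of the case's heterogeneous driver); one private clone per retained region
at CCF 0.4; and, for each clonal mutant-lost LOH event, a "shadow" set of
mutations drawn from the **non-trunk** budget and placed inside the LOH
interval, present in every region except the affected one. That bookkeeping
mirrors the study's own accounting — mutations deleted in one region are
counted in the heterogeneous compartment — and keeps the configured trunk
fraction equal to the measured truth. The same interval carries a 50/50
subclonal LOH in a second region, halving those mutations' VAF there.

Read model: expected alt fraction `p = purity × CCF × m / 2` with effective
multiplicity m = 1 on neutral territory, m = 1−f under a mutant-lost LOH
carried by a fraction f of tumor cells (f = 1 → absent; f = 0.5 → half VAF),
m = 1+f under wild-type-lost LOH, and m = 2/(2 − f·purity) under hemizygous
deletion (which retains the mutated homolog — the generator expresses
mutant-allele removal only through explicit LOH events, so a focal deletion
cannot silently corrupt the configured trunk fraction). Depth is negative
binomial; alt counts binomial given depth; DNV members share a clone and
hence an expected VAF. Single-copy gains shift VAF by ≤15% at default purity
and are left unadjusted.

Because the CC>TT share of DNVs (0.87) and the class UV fractions (0.80 /
0.57) are separate dials, the standalone-SNV UV probability is solved from
`p_uv·n_units = p_snv·n_snv_alone + cc_tt·n_dnv` (clipped to [0,1]) so the
class-level UV fraction over units converges to the configured value — the
recovery tests depend on that identity.

Copy-number tracks are 25-kb bins with Gaussian noise (sd 0.12, typical
shallow-WES scatter); event log2 values follow from region purity and event
copy number, `log2((2(1−purity) + cn·purity)/2)`. 25 kb rather than a
coarser grid gives the default segmentation parameters adequate power on the
1-Mb focal deletion (at 100 kb the first binary split cannot reach |t| ≥ 5).

`simulate_cohort` draws per-sample mutational load from a group-specific
negative binomial (defaults: mean 40 / 18, dispersion 0.25 — plausible for a
40-gene ultra-deep panel in heavily vs lightly sun-damaged skin) and gene
hits as independent Bernoulli per gene with group-specific probabilities
(defaults mirror the reported frequencies: NF1 0.35/0.08, TP53 0.48/0.12,
BRAF 0.39/0.53 with the V600K hotspot enriched in the CSD-high group).

**What the generator does not emulate** — and hence what passing recovery
tests do not demonstrate about real data: sequencing error and artifact
modes (no false-positive candidate variants), germline contamination,
mappability structure, correlated depth along the genome, subclonal copy
number beyond the configured events, more than two levels of clonal nesting,
and inter-gene mutation correlation in cohorts. Recovery results bound what
the pipeline can do when its read model holds, not when it is violated.

## Problem sizes in tests and acceptance

The test suite and `scripts/acceptance.py` run the case at its natural size
(1,844 mutations, 12 regions), the UV-recovery check at 5,000 mutations
(the non-trunk arm at 1,844 holds only ~70 substitution units, making a
3-SE check and an α = 0.001 contrast underpowered at the natural size — the
corresponding printed p is itself only 1×10⁻⁴), LOH-verdict rates over 100
replicates of an 800-mutation case, oracle equivalence over 500 Fisher
tables / 60 rank-sum pairs / 200 parsimony instances, and type-I error over
1,000 simulated 72-sample cohorts.

## Known limitations

- Presence calling is threshold-based; no probabilistic genotype model, and
  thresholds are not calibrated per-region to depth or purity.
- Purity estimation assumes diploid-heterozygous trunk sites; heavily
  aneuploid genomes would bias it (copy-neutral restriction mitigates only
  where segments are supplied).
- The tree builder is exact only on the refined conflict set; with more than
  12 conflicting patterns it falls back to greedy order.
- UV attribution is context-only; it does not deconvolve full mutational
  signatures and will misattribute non-UV dipyrimidine C>T.
- Segmentation has no per-bin variance model (GC, mappability) and the
  gain/loss thresholds assume near-diploid ploidy.
- The subclonal-mixture verdict inherits the rank-sum test's ~2.5% per-region
  false-positive rate at the 0.05 level; screening many regions needs a
  multiplicity correction the package does not impose.
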