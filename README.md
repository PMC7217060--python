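# melith

Multi-region genetic heterogeneity analysis for melanoma, plus cohort-level
mutation statistics.

When several regions of one patient's primary tumor and its in-transit
metastases are sequenced against a matched normal, the somatic mutations
partition into **trunk** (present in every specimen — acquired before the
regions diverged), **branch** (shared by some but not all), and **private**
(confined to one specimen). The size of the non-trunk compartment measures
intra-tumor heterogeneity (ITH); its substitution spectrum, compared with the
trunk's, says *when* the mutagenic exposure acted. In chronically sun-damaged
(CSD) melanoma the dominant process is ultraviolet light, whose fingerprint is
C>T at dipyrimidine sites (5′ pyrimidine) and CC>TT tandem dinucleotide
substitutions. Copy-number analysis closes the loop: an apparent branch
mutation may be a clonal mutation that a region-specific deletion (loss of
heterozygosity, LOH) removed or diluted, which the package detects by
comparing variant allele frequencies (VAF) of branch vs trunk mutations on
the affected chromosome.

`melith` implements that entire analysis as a tested library for people who
study tumor evolution from multi-region sequencing:

- **presence calling** with asymmetric evidence thresholds (strict de novo,
  lenient cross-region *rescue*) so depth fluctuations do not fabricate
  heterogeneity, plus purity estimation (purity = 2 × median VAF of
  near-ubiquitous variants under the heterozygous-diploid assumption) and
  exclusion of low-purity specimens;
- **trunk/branch/private classification** and a maximum-parsimony phylogeny
  over binary presence patterns (greedy laminar-family construction with
  exhaustive refinement of conflicts; branch length = mutation count;
  Newick output);
- **mutational signatures**: pyrimidine-strand spectra with C>T split by 5′
  purine/pyrimidine × 3′ G, DNV/CC>TT detection, UV attribution, and exact /
  Monte-Carlo Fisher spectrum comparisons;
- **copy number**: recursive binary segmentation of binned log2 ratios
  (split at the maximal Welch *t*), gain/loss calling, shared-vs-heterogeneous
  aberration tables, and branch-vs-trunk VAF reconciliation with verdicts
  `loh_removed` / `subclonal_mixture` / `concordant`;
- **cohort statistics**: per-gene mutation frequencies and hotspot codon
  composition (exact Fisher), mutational-load comparisons (exact rank-sum
  where feasible);
- a **synthetic-data generator** (`melith.simcase`) that emulates the study
  conditions — 12 regions (5 primary-tumor, 7 in-transit) with two low-purity
  specimens, 1,844 mutations at 96.2% trunk fraction, UV fractions 0.80
  (trunk) / 0.57 (non-trunk), 9% DNVs with 87% CC>TT, ~100× overdispersed
  depth, a region-subset focal deletion and clonal/subclonal LOH — with full
  ground truth for recovery testing.

## Worked example

Simulate the default case and run the full chain (presence calling → purity
exclusion → classification → phylogeny → signatures → segmentation → VAF
reconciliation):

```yaml
# case.yaml
seed: 31
simulate: {n_mutations: 1844, seed: 31}
reconcile: {chrom: chr14, regions: [PT4, IT2, PT3]}
loci:
  - {chrom: chr9, start: 2400000, end: 2600000, name: CDKN2A_analog}
```

```bash
melith run-case --config case.yaml --out out
# {"trunk_percent": 96.2, "heterogeneous_percent": 3.8}
```

`out/report.json` from that run contains (abridged):

```
classes:     trunk 1774 (96.2%), branch 31 (1.7%), private 39 (2.1%)  -> heterogeneous 3.8%
excluded:    PT1, IT6            (estimated purity 0.15, below the 0.2 floor)
dnv:         153 DNVs among 1819 SNVs, 132 (86%) CC>TT
uv:          trunk 81% vs non-trunk 53% UV-attributable; 2x2 Fisher p = 4.6e-07
tree:        13 clades, 0 homoplasy, parsimony cost 1844
vaf (chr14): PT4 loh_removed (branch muts absent),
             IT2 subclonal_mixture (branch median VAF 14% vs trunk 31%),
             PT3 concordant (31% vs 29%)
cna:         CDKN2A_analog loss heterogeneous (IT1, IT3, IT7 only)
```

Read: ~96% of mutations are in every retained specimen, so the lesions share
one clonal origin and little has diverged since. The non-trunk compartment is
significantly depleted of the UV fingerprint — late mutations arose after the
UV exposure that built the trunk. On chr14 the same branch mutations are
*absent* in PT4 (the deletion removed the mutant allele) but present at half
VAF in IT2 (a 50/50 mixture of cells with and without the deletion): copy
number, not mutation timing, explains that slice of the heterogeneity.

The cohort side works the same way (`melith run-cohort`), or directly:

```python
from melith import cohortstats, simcase
df = simcase.simulate_cohort(n_high=23, n_low=49, seed=41)
cohort = cohortstats.cohort_from_table(df)
cohortstats.gene_freq_test(cohort, "NF1")["p"]     # Fisher, mutant counts by CSD class
cohortstats.compare_load(cohort)["p"]              # rank-sum on mutational load
```

## Layout

| module | contents |
|---|---|
| `melith.variant_io` | VCF/SEG/TSV/Newick readers and writers, core containers |
| `melith.regioncalls` | presence calling, rescue, purity estimation/exclusion |
| `melith.clonality` | trunk/branch/private classes, parsimony tree, PT-vs-IT test |
| `melith.mutsig` | spectra, DNV/CC>TT detection, UV attribution, comparisons |
| `melith.cnahet` | segmentation, CNA calls, region comparison, VAF reconciliation |
| `melith.cohortstats` | gene frequency / codon / load statistics |
| `melith.simcase` | synthetic case and cohort generator with ground truth |
| `melith.reference` | brute-force oracles (enumeration, permutation, tree search) |
| `melith.cli` | `melith run-case` / `run-cohort` / `simulate` |

See `docs/methods.md` for the model assumptions, parameter choices and known
limitations.
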