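import numpy as np
import pandas as pd
import pytest

from melith import clonality, regioncalls, simcase
from melith.simcase import CNAEvent, SimConfig, simulate_case, simulate_cohort

from conftest import run_pipeline


class TestConfigValidation:
    def test_trunk_budget_below_one_rejected(self):
        with pytest.raises(ValueError, match="at least 1"):
            SimConfig(seed=1, n_mutations=10, trunk_fraction=0.01,
                      n_insertions=0, n_deletions=0)

    def test_purity_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="purity"):
            SimConfig(seed=1, n_regions=4, purity_per_region=[0.5, 0.5])

    def test_proportions_bounded(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, p_uv_trunk=1.2)

    def test_overlapping_events_on_same_region_rejected(self):
        events = [
            CNAEvent("chr9", 0, 2_000_000, ("IT1",), "loss"),
            CNAEvent("chr9", 1_000_000, 3_000_000, ("IT1", "IT2"), "loss"),
        ]
        with pytest.raises(ValueError, match="overlapping"):
            SimConfig(seed=1, cna_events=events)

    def test_same_interval_disjoint_regions_allowed(self):
        events = [
            CNAEvent("chr14", 0, 1_000_000, ("PT4",), "loh", fraction=1.0),
            CNAEvent("chr14", 0, 1_000_000, ("IT2",), "loh", fraction=0.5),
        ]
        SimConfig(seed=1, cna_events=events)  # no error

    def test_cohort_requires_seed(self):
        with pytest.raises(ValueError, match="seed"):
            simulate_cohort(5, 5, seed=None)

    def test_cohort_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            simulate_cohort(-1, 5, seed=1)


class TestDeterminism:
    def test_identical_seed_identical_outputs(self):
        cfg1 = SimConfig(seed=42, n_mutations=300)
        cfg2 = SimConfig(seed=42, n_mutations=300)
        m1, b1, t1 = simulate_case(cfg1)
        m2, b2, t2 = simulate_case(cfg2)
        assert m1 == m2
        assert b1.equals(b2)
        assert t1.mutations.equals(t2.mutations)
        assert t1.dnv_pairs == t2.dnv_pairs

    def test_different_seed_different_reads(self):
        m1, _, _ = simulate_case(SimConfig(seed=1, n_mutations=200))
        m2, _, _ = simulate_case(SimConfig(seed=2, n_mutations=200))
        assert not np.array_equal(m1.alt, m2.alt)

    def test_cohort_deterministic(self):
        df1 = simulate_cohort(12, 12, seed=7)
        df2 = simulate_cohort(12, 12, seed=7)
        assert df1.equals(df2)


class TestCaseTruth:
    def test_case_study_trunk_count(self):
        cfg = SimConfig(seed=3, n_mutations=1844, trunk_fraction=0.962)
        _, _, truth = simulate_case(cfg)
        assert truth.mutation_class.count("trunk") == 1774

    def test_degenerate_all_trunk(self):
        cfg = SimConfig(seed=4, n_mutations=120, trunk_fraction=1.0,
                        cna_events=[], n_insertions=0, n_deletions=0)
        _, _, truth, _, retained, annotations = run_pipeline(cfg)
        s = clonality.summarize_classes(annotations)
        assert s["trunk"]["percent"] == 100.0
        assert s["heterogeneous"]["count"] == 0

    def test_every_mutation_maps_to_a_known_clone(self, default_case):
        truth = default_case["truth"]
        for clone in truth.mutation_clone:
            assert clone in truth.clone_tree

    def test_region_mix_is_a_proper_mixture(self, default_case):
        truth = default_case["truth"]
        for region, mix in truth.region_clone_mix.items():
            assert sum(mix.values()) <= 1.0 + 1e-9
            assert mix.get("trunk", 0) > 0

    def test_truth_present_implies_positive_expected_vaf(self, default_case):
        truth = default_case["truth"]
        matrix = default_case["matrix"]
        ev = truth.expected_vaf
        # trunk mutations outside the clonal-LOH interval: positive
        # expected VAF in every region
        for i, clone in enumerate(truth.mutation_clone):
            if clone == "trunk":
                assert (ev[i] > 0).all()
        # the LOH-shadow clone is absent exactly where the event removed it
        shadow = [i for i, c in enumerate(truth.mutation_clone)
                  if c.startswith("loh_shadow")]
        j_pt4 = matrix.regions.index("PT4")
        assert all(ev[i, j_pt4] == 0 for i in shadow)
        j_pt3 = matrix.regions.index("PT3")
        assert all(ev[i, j_pt3] > 0 for i in shadow)

    def test_dnv_pairs_are_adjacent_same_clone(self, default_case):
        truth = default_case["truth"]
        matrix = default_case["matrix"]
        for a, b in truth.dnv_pairs:
            va, vb = matrix.variants[a], matrix.variants[b]
            assert va.chrom == vb.chrom and vb.pos == va.pos + 1
            assert truth.mutation_clone[a] == truth.mutation_clone[b]

    def test_low_purity_regions_marked_for_exclusion(self, default_case):
        assert default_case["truth"].region_excluded_expected == ["PT1", "IT6"]


class TestSpectrumControl:
    def test_uv_fractions_converge_to_configuration(self):
        """Generated trunk / non-trunk UV unit fractions approach the
        configured probabilities (3 binomial SE at the realised unit counts)."""
        cfg = SimConfig(seed=17, n_mutations=4000)
        _, _, truth = simulate_case(cfg)
        df = truth.mutations
        snv = df[~df.is_indel].copy()
        # one unit per standalone SNV, one per DNV pair
        units = []
        seen_pair = set()
        for i, row in snv.iterrows():
            if row.is_dnv_member:
                pair = next(p for p in truth.dnv_pairs if i in p)
                if pair in seen_pair:
                    continue
                seen_pair.add(pair)
            units.append((row.clonal_class == "trunk", bool(row.is_uv_unit)))
        for is_trunk, p_target in ((True, cfg.p_uv_trunk), (False, cfg.p_uv_nontrunk)):
            got = [uv for t, uv in units if t == is_trunk]
            se = (p_target * (1 - p_target) / len(got)) ** 0.5
            assert abs(np.mean(got) - p_target) <= 3 * se

    def test_cc_tt_share_of_dnvs_near_configuration(self):
        cfg = SimConfig(seed=19, n_mutations=4000)
        _, _, truth = simulate_case(cfg)
        df = truth.mutations
        members = df[df.is_dnv_member]
        share = members.is_uv_unit.mean()  # CC>TT flag is the pair's UV flag
        se = (0.87 * 0.13 / (len(members) / 2)) ** 0.5
        assert abs(share - cfg.cc_tt_fraction) <= 3 * se


class TestCohortGeneration:
    def test_expected_gene_counts(self):
        # NF1 high 0.35 (n=23), low 0.08 (n=49): expectations 8.05 / 3.92
        probs = {"NF1": {"CSD_high": 0.35, "CSD_low": 0.08}}
        highs, lows = [], []
        for seed in range(40):
            df = simulate_cohort(23, 49, gene_probs=probs, seed=seed)
            nf1 = df[df.gene == "NF1"]
            highs.append((nf1.group == "CSD_high").sum())
            lows.append((nf1.group == "CSD_low").sum())
        se_h = (23 * 0.35 * 0.65 / 40) ** 0.5
        se_l = (49 * 0.08 * 0.92 / 40) ** 0.5
        assert abs(np.mean(highs) - 8.05) <= 3 * se_h
        assert abs(np.mean(lows) - 3.92) <= 3 * se_l

    def test_all_zero_probabilities_give_no_gene_rows(self):
        probs = {"NF1": {"CSD_high": 0.0, "CSD_low": 0.0}}
        df = simulate_cohort(10, 10, gene_probs=probs, seed=5)
        assert (df.gene == "").all()
        assert len(df) == 20  # metadata rows survive

    def test_one_row_per_sample_gene_hit(self):
        df = simulate_cohort(30, 30, seed=8)
        with_gene = df[df.gene != ""]
        assert not with_gene.duplicated(["sample_id", "gene"]).any()


class TestOutputs:
    def test_written_files_round_trip(self, tmp_path):
        from melith.variant_io import read_multisample_vcf, read_sample_sheet

        cfg = SimConfig(seed=6, n_mutations=80)
        matrix, bins, truth = simulate_case(cfg)
        simcase.write_case_outputs(matrix, bins, truth, cfg, tmp_path)
        back = read_multisample_vcf(tmp_path / "case.vcf")
        assert back.n_variants == matrix.n_variants
        sheet = read_sample_sheet(tmp_path / "sample_sheet.tsv")
        assert list(sheet["region_id"]) == cfg.region_ids
        truth_df = pd.read_csv(tmp_path / "mutation_truth.tsv", sep="\t")
        assert len(truth_df) == 80
        assert (tmp_path / "sim_config.yaml").exists()
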