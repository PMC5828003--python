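"""Generator contracts: LD structure, planted signals, determinism."""

import filecmp

import numpy as np
import pytest

from regshare.ld_ops import compute_r2, r2_matrix
from regshare.synthetic_data import (
    LdBlockSpec,
    PlantedTruth,
    StudyParams,
    simulate_gwas_summaries,
    simulate_haplotype_panel,
    simulate_pathways,
    simulate_regulatory_catalogs,
    simulate_study,
)


class TestHaplotypePanelSimulation:
    def test_perfect_ld_block_is_copy_construction(self):
        spec = LdBlockSpec(n_blocks=1, snps_per_block=3, within_block_r2=1.0)
        panel = simulate_haplotype_panel(spec, 100, seed=0)
        cols = [panel.matrix[:, i] for i in range(3)]
        assert np.array_equal(cols[0], cols[1])
        assert np.array_equal(cols[1], cols[2])
        assert compute_r2(cols[0], cols[1]) == 1.0

    def test_zero_target_r2_gives_near_independent_columns(self):
        spec = LdBlockSpec(n_blocks=1, snps_per_block=15, within_block_r2=0.0)
        panel = simulate_haplotype_panel(spec, 1000, seed=1)
        r2 = r2_matrix(panel.matrix, range(panel.n_variants))
        off = r2[~np.eye(panel.n_variants, dtype=bool)]
        # oracle: independent Bernoulli columns; mean off-diagonal r2
        # is approx 1/n_haplotypes, well under 0.05
        assert np.nanmean(off) < 0.05

    def test_target_r2_is_approximately_achieved(self):
        spec = LdBlockSpec(n_blocks=4, snps_per_block=6, within_block_r2=0.8)
        panel = simulate_haplotype_panel(spec, 2000, seed=2)
        vals = []
        for b in range(4):
            idx = range(b * 6, (b + 1) * 6)
            r2 = r2_matrix(panel.matrix, idx)
            vals.append(np.nanmean(r2[~np.eye(6, dtype=bool)]))
        assert np.mean(vals) == pytest.approx(0.8, abs=0.1)

    def test_blocks_are_mutually_independent(self):
        spec = LdBlockSpec(n_blocks=10, snps_per_block=2, within_block_r2=1.0)
        panel = simulate_haplotype_panel(spec, 1000, seed=3)
        first_of_block = list(range(0, 20, 2))
        r2 = r2_matrix(panel.matrix, first_of_block)
        off = r2[~np.eye(10, dtype=bool)]
        assert np.nanmax(off) < 0.1

    def test_same_seed_identical_matrices(self):
        spec = LdBlockSpec(n_blocks=3, snps_per_block=4)
        a = simulate_haplotype_panel(spec, 60, seed=9)
        b = simulate_haplotype_panel(spec, 60, seed=9)
        assert np.array_equal(a.matrix, b.matrix)

    def test_odd_or_tiny_haplotype_count_rejected(self):
        spec = LdBlockSpec()
        with pytest.raises(ValueError):
            simulate_haplotype_panel(spec, 5, seed=0)
        with pytest.raises(ValueError):
            simulate_haplotype_panel(spec, 2, seed=0)

    def test_infeasible_maf_range_rejected(self):
        with pytest.raises(ValueError, match="maf_range"):
            LdBlockSpec(maf_range=(0.4, 0.2))


class TestGwasSummarySimulation:
    @pytest.fixture
    def panel_and_truth(self):
        spec = LdBlockSpec(n_blocks=6, snps_per_block=4)
        panel = simulate_haplotype_panel(spec, 100, seed=4)
        truth = PlantedTruth(
            shared_signal_snps=frozenset({"rs1"}),
            unique_signal_snps={"LUAD": frozenset({"rs5"}),
                                "LUSC": frozenset({"rs9"})},
            shared_target_genes=frozenset({"G1"}),
            unique_target_genes={"LUAD": frozenset({"G2"}),
                                 "LUSC": frozenset({"G3"})},
            enriched_pathway_id="PW",
        )
        return panel, truth

    def test_planted_snps_pass_selection_with_certainty(self, panel_and_truth):
        panel, truth = panel_and_truth
        gwas = simulate_gwas_summaries(panel, truth, alpha_signal=1e-4, seed=0)
        luad = {s.rsid: s.pvalue for s in gwas["LUAD"]}
        assert luad["rs1"] < 1e-3 and luad["rs5"] < 1e-3
        assert len(gwas["LUAD"]) == panel.n_variants

    def test_null_pass_rate_matches_binomial_expectation(self):
        spec = LdBlockSpec(n_blocks=100, snps_per_block=10, within_block_r2=0.0)
        panel = simulate_haplotype_panel(spec, 10, seed=5)
        truth = PlantedTruth(frozenset(), {"X": frozenset(), "Y": frozenset()},
                             frozenset(), {"X": frozenset(), "Y": frozenset()},
                             "PW")
        n_pass = 0
        n_total = 0
        for seed in range(10):
            gwas = simulate_gwas_summaries(panel, truth, seed=seed)
            for phen in ("X", "Y"):
                n_pass += sum(s.pvalue < 1e-3 for s in gwas[phen])
                n_total += len(gwas[phen])
        expected = 1e-3 * n_total
        sigma = np.sqrt(n_total * 1e-3 * (1 - 1e-3))
        assert abs(n_pass - expected) <= 3 * sigma

    def test_empty_truth_gives_all_null(self, panel_and_truth):
        panel, _ = panel_and_truth
        truth = PlantedTruth(frozenset(), {"X": frozenset()}, frozenset(),
                             {"X": frozenset()}, "PW")
        gwas = simulate_gwas_summaries(panel, truth, alpha_signal=1e-6, seed=0)
        assert sum(s.pvalue < 1e-6 for s in gwas["X"]) == 0

    def test_unknown_planted_rsid_rejected(self, panel_and_truth):
        panel, _ = panel_and_truth
        truth = PlantedTruth(frozenset({"rs_nope"}), {"X": frozenset()},
                             frozenset(), {"X": frozenset()}, "PW")
        with pytest.raises(ValueError, match="rs_nope"):
            simulate_gwas_summaries(panel, truth, seed=0)

    def test_shared_and_unique_snps_must_be_disjoint(self):
        with pytest.raises(ValueError, match="disjoint"):
            PlantedTruth(frozenset({"rs1"}), {"X": frozenset({"rs1"})},
                         frozenset(), {"X": frozenset()}, "PW")


class TestRegulatoryCatalogSimulation:
    def test_every_planted_gene_reachable_with_passing_score(self, study):
        truth = study.truth
        cats = study.catalogs
        reachable = {r.gene for r in cats.single_tissue
                     if r.qvalue is not None and r.qvalue <= 0.05}
        reachable |= {r.gene for r in cats.multi_tissue
                      if r.posterior is not None and r.posterior > 0.8}
        reachable |= {r.gene for r in cats.probe if r.gene}
        reachable |= {a.target for a in cats.fantom_associations}
        reachable |= {cats.tx2gene[p.target] for p in cats.impet_pairs
                      if p.target in cats.tx2gene and p.rpkm}
        for gene in truth.shared_target_genes:
            assert gene in reachable
        for phen in truth.phenotypes:
            assert truth.unique_target_genes[phen] <= reachable

    def test_decoy_rows_fail_their_filters(self, study):
        cats = study.catalogs
        decoy_single = [r for r in cats.single_tissue
                        if r.gene.startswith("DECOY")]
        assert decoy_single and all(r.qvalue > 0.05 for r in decoy_single)
        decoy_multi = [r for r in cats.multi_tissue
                       if r.gene.startswith("DECOY")]
        assert decoy_multi and all(r.posterior <= 0.8 for r in decoy_multi)

    def test_same_seed_byte_identical_files(self, study, tmp_path):
        a = tmp_path / "a"
        b = tmp_path / "b"
        paths_a = study.catalogs.write(a)
        paths_b = study.catalogs.write(b)
        for key in paths_a:
            assert filecmp.cmp(paths_a[key], paths_b[key], shallow=False), key

    def test_gene_absent_from_models_rejected(self, study):
        truth = PlantedTruth(
            study.truth.shared_signal_snps,
            study.truth.unique_signal_snps,
            frozenset({"NOT_A_GENE"}),
            study.truth.unique_target_genes,
            "PW",
        )
        with pytest.raises(ValueError, match="NOT_A_GENE"):
            simulate_regulatory_catalogs(study.panel, study.gene_models, truth)


class TestPathwaySimulation:
    def test_planted_pathway_contains_all_shared_targets(self, study):
        planted = study.pathways[study.truth.enriched_pathway_id]
        assert study.truth.shared_target_genes <= planted

    def test_single_pathway_collection(self, study):
        coll = simulate_pathways(
            sorted({m.gene for m in study.gene_models}), study.truth,
            n_pathways=1, seed=0)
        assert len(coll) == 1

    def test_universe_smaller_than_sizes_rejected(self, study):
        with pytest.raises(ValueError, match="universe"):
            simulate_pathways(["A", "B"] + sorted(
                study.truth.shared_target_genes
                | set().union(*study.truth.unique_target_genes.values())),
                study.truth, n_pathways=3, seed=0, size_range=(10, 30))


class TestStudyDeterminism:
    def test_same_seed_reproduces_study_files(self, tmp_path):
        params = StudyParams(ld=LdBlockSpec(n_blocks=12, snps_per_block=4),
                             n_haplotypes=80, n_decoy_genes=30)
        a_dir, b_dir = tmp_path / "a", tmp_path / "b"
        paths_a = simulate_study(params, seed=5).write(a_dir)
        paths_b = simulate_study(params, seed=5).write(b_dir)
        for key in paths_a:
            assert filecmp.cmp(paths_a[key], paths_b[key], shallow=False), key
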