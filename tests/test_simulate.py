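"""The synthetic-study generator: determinism, planted structure, and the
statistical properties downstream stages rely on."""

import numpy as np
import pytest
from scipy import stats

from choreseq.core_io import tss_of
from choreseq.simulate import (
    SimulationConfig,
    make_genome_and_genes,
    plant_binding_sites,
    simulate_expression,
    simulate_study,
    simulate_tag_arrays,
    simulate_tags,
)

SMALL = dict(genome_size=120_000, gene_count=10, n_sites=5,
             n_chip_tags=5_000, n_input_tags=5_000)


class TestGenomeAndGenes:
    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=1, **SMALL)
        g1, genes1 = make_genome_and_genes(cfg)
        g2, genes2 = make_genome_and_genes(cfg)
        assert g1.sequences == g2.sequences
        assert genes1 == genes2

    def test_gc_content_within_binomial_bound(self):
        cfg = SimulationConfig(seed=2, genome_size=1_000_000, gene_count=1,
                               gc=0.5)
        genome, _ = make_genome_and_genes(cfg)
        seq = genome["chr1"]
        gc = sum(c in "GC" for c in seq)
        n = len(seq)
        # 99% binomial interval around 0.5
        half = 2.576 * np.sqrt(0.25 / n)
        assert abs(gc / n - 0.5) < half

    def test_zero_genes(self):
        cfg = SimulationConfig(seed=3, genome_size=10_000, gene_count=0)
        genome, genes = make_genome_and_genes(cfg)
        assert genes == [] and len(genome["chr1"]) == 10_000

    def test_overfull_genome_raises(self):
        cfg = SimulationConfig(seed=4, genome_size=20_000, gene_count=50)
        with pytest.raises(ValueError, match="larger genome"):
            make_genome_and_genes(cfg)

    def test_genes_disjoint_with_two_exons(self):
        cfg = SimulationConfig(seed=5, **SMALL)
        _, genes = make_genome_and_genes(cfg)
        assert len(genes) == 10
        spans = sorted((g.tx_start, g.tx_end) for g in genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2
        assert all(len(g.exons) >= 2 for g in genes)


class TestPlantSites:
    def test_consensus_written_into_genome(self):
        cfg = SimulationConfig(seed=6, **{**SMALL, "n_sites": 10},
                               plant_strand="plus")
        genome, genes = make_genome_and_genes(cfg)
        genome, sites = plant_binding_sites(
            genome, genes, "CACGTGGCCGGCGCGTG", cfg
        )
        assert len(sites) == 10
        for s in sites:
            assert genome.fetch(s.chrom, s.position, s.position + 17) == \
                "CACGTGGCCGGCGCGTG"

    def test_zero_sites_genome_unchanged(self):
        cfg = SimulationConfig(seed=7, **{**SMALL, "n_sites": 0})
        genome, genes = make_genome_and_genes(cfg)
        before = dict(genome.sequences)
        genome2, sites = plant_binding_sites(genome, genes, "CACGTG", cfg)
        assert sites == [] and genome2.sequences == before

    def test_degenerate_placement_at_fixed_offset(self):
        cfg = SimulationConfig(
            seed=8, **SMALL, tss_offset_mean=-1_000, tss_offset_sd=0.0,
            plant_strand="plus",
        )
        genome, genes = make_genome_and_genes(cfg)
        genome, sites = plant_binding_sites(genome, genes, "CACGTG", cfg)
        by_id = {g.gene_id: g for g in genes}
        for s in sites:
            g = by_id[s.linked_gene_id]
            if g.strand == "+":
                assert s.position == tss_of(g) - 1_000


class TestSimulateTags:
    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=9, **SMALL)
        genome, genes = make_genome_and_genes(cfg)
        genome, sites = plant_binding_sites(genome, genes, "CACGTG", cfg)
        c1, i1 = simulate_tags(genome, sites, cfg)
        c2, i2 = simulate_tags(genome, sites, cfg)
        assert c1 == c2 and i1 == i2

    def test_zero_tags(self):
        cfg = SimulationConfig(seed=10, **{**SMALL,
                                           "n_chip_tags": 0,
                                           "n_input_tags": 0})
        genome, genes = make_genome_and_genes(cfg)
        chip, inp = simulate_tags(genome, [], cfg)
        assert chip == [] and inp == []

    def test_null_chip_exchangeable_with_input(self):
        """With no site-derived tags, ChIP and input positions are draws from
        the same distribution (two-sample KS non-significant in most seeds)."""
        L = {"chr1": 200_000}
        passed = 0
        n_rep = 20
        for s in range(n_rep):
            cfg = SimulationConfig(seed=100 + s, chip_enrichment=0.0,
                                   n_chip_tags=2_000, n_input_tags=2_000)
            cs, _, is_, _ = simulate_tag_arrays(L, [], cfg)
            ks = stats.ks_2samp(cs["chr1"], is_["chr1"])
            if ks.pvalue > 0.01:
                passed += 1
        assert passed >= int(0.95 * n_rep) - 1

    def test_site_tags_concentrate_at_site_center(self):
        """Modal coverage sits within +-50 bp of the planted site centre."""
        cfg = SimulationConfig(
            seed=11, **{**SMALL, "n_sites": 1, "n_chip_tags": 10_000},
            chip_enrichment=0.9,
        )
        genome, genes = make_genome_and_genes(cfg)
        genome, sites = plant_binding_sites(genome, genes, "CACGTG", cfg)
        from choreseq.peaks import build_coverage

        chip, _ = simulate_tags(genome, sites, cfg)
        cov = build_coverage(chip, 200, genome.lengths)
        modal = int(np.argmax(cov["chr1"]))
        assert abs(modal - sites[0].center) <= 50


class TestSimulateExpression:
    def _genes(self, n):
        cfg = SimulationConfig(seed=1, genome_size=20_000 * n, gene_count=n)
        _, genes = make_genome_and_genes(cfg)
        return genes

    def test_fraction_up_one(self):
        genes = self._genes(20)
        cfg = SimulationConfig(seed=12, fraction_up=1.0)
        bound = [g.gene_id for g in genes[:10]]
        _, _, truth = simulate_expression(genes, bound, cfg)
        assert (truth.loc[bound, "direction"] == "up").all()

    def test_strong_effects_dominate_fold_change(self):
        """Effect 4 at sd 0.1 forces every bound gene into the top decile."""
        genes = self._genes(100)
        cfg = SimulationConfig(seed=13, effect_size=4.0, noise_sd=0.1,
                               indep_de_fraction=0.0)
        bound = [g.gene_id for g in genes[:10]]
        m, cond, truth = simulate_expression(genes, bound, cfg)
        from choreseq.expression import compute_fold_changes

        fc = compute_fold_changes(m, cond).abs().sort_values(ascending=False)
        top_decile = set(fc.index[:10])
        assert set(bound) == top_decile

    def test_replicates_below_two(self):
        genes = self._genes(5)
        cfg = SimulationConfig(seed=14)
        cfg.replicates = 1
        with pytest.raises(ValueError, match="replicates"):
            simulate_expression(genes, [], cfg)

    def test_unknown_bound_gene(self):
        genes = self._genes(5)
        cfg = SimulationConfig(seed=15)
        with pytest.raises(ValueError, match="not in gene list"):
            simulate_expression(genes, ["nope"], cfg)


class TestSimulateStudy:
    def test_full_reproducibility(self):
        cfg = SimulationConfig(seed=16, **SMALL)
        s1 = simulate_study(cfg)
        s2 = simulate_study(cfg)
        assert s1.genome.sequences == s2.genome.sequences
        assert s1.sites == s2.sites
        assert s1.chip_tags == s2.chip_tags
        assert s1.expression.equals(s2.expression)

    def test_truth_files_written(self, tmp_path):
        cfg = SimulationConfig(seed=17, **SMALL)
        study = simulate_study(cfg)
        study.write(tmp_path)
        for name in ("genome.fa", "genes.bed", "chip.bed", "input.bed",
                     "expression.tsv", "sites.tsv", "bound_genes.tsv"):
            assert (tmp_path / name).exists()

    def test_decoupled_bound_genes_not_de(self):
        cfg = SimulationConfig(seed=18, **SMALL)
        study = simulate_study(cfg, decouple_expression=True)
        bound = set(study.bound_gene_ids)
        de_truth = set(study.truth.index[study.truth["direction"] != "none"])
        assert not (bound & de_truth)
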