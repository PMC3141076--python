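"""Fold changes, moderated t, beta-uniform mixture PPDE and ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from choreseq.core_io import GeneModel
from choreseq.expression import (
    compute_fold_changes,
    de_gene_list,
    fit_bum,
    moderated_t_ppde,
    rank_genes,
)
from choreseq.simulate import SimulationConfig, simulate_expression


def _genes(n):
    return [
        GeneModel(f"g{i:04d}", "chr1", "+", i * 1000, i * 1000 + 500,
                  ((i * 1000, i * 1000 + 500),))
        for i in range(n)
    ]


def _matrix(values: dict[str, list[float]], reps=3):
    cols = [f"low_{i+1}" for i in range(reps)] + [f"high_{i+1}" for i in range(reps)]
    df = pd.DataFrame(values, index=cols).T
    return df, ["low"] * reps + ["high"] * reps


class TestFoldChanges:
    def test_equal_means_zero(self):
        m, cond = _matrix({"g1": [8, 8, 8, 8, 8, 8]})
        assert compute_fold_changes(m, cond)["g1"] == 0

    def test_two_unit_shift(self):
        m, cond = _matrix({"g1": [8, 8, 8, 10, 10, 10]})
        assert compute_fold_changes(m, cond)["g1"] == 2

    def test_label_swap_flips_sign(self):
        rng = np.random.default_rng(0)
        vals = {f"g{i}": list(rng.normal(8, 1, 6)) for i in range(10)}
        m, cond = _matrix(vals)
        fc = compute_fold_changes(m, cond, order=("low", "high"))
        swapped = ["high" if c == "low" else "low" for c in cond]
        fc_swapped = compute_fold_changes(m, swapped, order=("low", "high"))
        np.testing.assert_allclose(fc.to_numpy(), -fc_swapped.to_numpy())


class TestModeratedT:
    def test_nu0_zero_equals_ordinary_t(self):
        genes = _genes(300)
        cfg = SimulationConfig(seed=5)
        m, cond, _ = simulate_expression(genes, [g.gene_id for g in genes[:30]], cfg)
        de = moderated_t_ppde(m, cond, prior_df=0)
        t_ref, p_ref = stats.ttest_ind(
            m.iloc[:, 6:], m.iloc[:, :6], axis=1, equal_var=True
        )
        np.testing.assert_allclose(de.frame["t"].to_numpy(), t_ref, atol=1e-12)
        np.testing.assert_allclose(de.frame["p"].to_numpy(), p_ref, atol=1e-12)

    def test_null_pvalues_uniform(self):
        """Global null: p-values pass KS uniformity in nearly every seed."""
        genes = _genes(2000)
        passed = 0
        n_seed = 10
        for s in range(n_seed):
            cfg = SimulationConfig(seed=s, effect_size=0.0, indep_de_fraction=0.0)
            m, cond, _ = simulate_expression(genes, [], cfg)
            de = moderated_t_ppde(m, cond)
            if stats.kstest(de.frame["p"], "uniform").pvalue > 0.01:
                passed += 1
        assert passed >= n_seed - 1

    def test_planted_effects_separate_ppde(self):
        genes = _genes(500)
        cfg = SimulationConfig(seed=3, effect_size=4.0, noise_sd=0.1,
                               indep_de_fraction=0.0)
        bound = [g.gene_id for g in genes[:50]]
        m, cond, truth = simulate_expression(genes, bound, cfg)
        de = moderated_t_ppde(m, cond)
        planted = de.frame.loc[truth["bound"], "ppde"]
        nulls = de.frame.loc[~truth["bound"], "ppde"]
        assert planted.min() > nulls.max()

    def test_zero_variance_with_nu0_zero_raises(self):
        m, cond = _matrix({"g1": [5, 5, 5, 7, 7, 7], "g2": [1, 1, 1, 1, 1, 1]})
        with pytest.raises(ValueError, match="variance"):
            moderated_t_ppde(m, cond, prior_df=0)

    def test_missing_replicates_dropped(self):
        m, cond = _matrix({"g1": [8, 8, 8, 9, 9, 9],
                           "g2": [8, np.nan, np.nan, 9, 9, 9],
                           "g3": [7, 8, 9, 9, 8, 7]})
        with pytest.warns(UserWarning, match="dropping"):
            de = moderated_t_ppde(m, cond)
        assert list(de.frame.index) == ["g1", "g3"]


class TestBum:
    def test_null_lambda_near_one(self):
        rng = np.random.default_rng(21)
        fit = fit_bum(rng.uniform(size=2000))
        assert 0.9 <= fit.lambda_ <= 1.0

    def test_signal_lambda_below_one(self):
        rng = np.random.default_rng(22)
        p = np.concatenate([
            rng.uniform(size=1500), rng.beta(0.08, 1.0, size=500)
        ])
        fit = fit_bum(p)
        assert fit.lambda_ < 0.95
        assert 0 < fit.a <= 0.8

    def test_ppde_monotone_in_p(self):
        rng = np.random.default_rng(23)
        p = np.concatenate([rng.uniform(size=800), rng.beta(0.1, 1, 200)])
        fit = fit_bum(p)
        grid = np.linspace(1e-12, 1, 500)
        ppde = fit.ppde(grid)
        assert np.all(np.diff(ppde) <= 1e-12)


class TestRanking:
    def _results(self):
        genes = _genes(200)
        cfg = SimulationConfig(seed=9, effect_size=3.0, noise_sd=0.3)
        m, cond, _ = simulate_expression(genes, [g.gene_id for g in genes[:20]], cfg)
        return moderated_t_ppde(m, cond)

    def test_order_matches_key(self):
        de = self._results()
        ranked = rank_genes(de, "ppde")
        vals = de.frame.loc[ranked, "ppde"].to_numpy()
        assert np.all(np.diff(vals) <= 1e-15)

    def test_row_permutation_invariance(self):
        de = self._results()
        ranked = rank_genes(de, "fold_change")
        shuffled = de.frame.sample(frac=1, random_state=0)
        de.frame = shuffled
        assert rank_genes(de, "fold_change") == ranked

    def test_all_equal_keys_lexicographic(self):
        m, cond = _matrix({"b": [8, 8, 8, 8, 8, 8],
                           "a": [8, 8, 8, 8, 8, 8],
                           "c": [8, 8, 8, 8, 8, 8]})
        m = m + np.random.default_rng(1).normal(0, 1e-9, m.shape)
        de = moderated_t_ppde(m, cond)
        de.frame["ppde"] = 0.5
        de.frame["log2fc"] = 0.0
        assert rank_genes(de, "ppde") == ["a", "b", "c"]

    def test_rank_column_is_permutation(self):
        de = self._results()
        ranks = sorted(de.frame["rank"])
        assert ranks == list(range(1, len(de.frame) + 1))


class TestDeGeneList:
    def test_exclusive_cutoff_empty(self):
        de = TestRanking()._results()
        up, down = de_gene_list(de, ppde_cutoff=1.0)
        strict = de.frame["ppde"] >= 1.0
        assert len(up) + len(down) == int(
            (strict & (de.frame["log2fc"] != 0)).sum()
        )

    def test_include_all_cutoff(self):
        de = TestRanking()._results()
        up, down = de_gene_list(de, ppde_cutoff=0.0)
        nonzero = (de.frame["log2fc"] != 0).sum()
        assert len(up) + len(down) == int(nonzero)

    def test_directional_split_matches_design(self):
        """Strong planted effects with fraction_up 0.5 recover a ~50/50 split."""
        genes = _genes(300)
        cfg = SimulationConfig(seed=10, effect_size=4.0, noise_sd=0.1,
                               indep_de_fraction=0.0)
        bound = [g.gene_id for g in genes[:40]]
        m, cond, truth = simulate_expression(genes, bound, cfg)
        de = moderated_t_ppde(m, cond)
        up, down = de_gene_list(de, ppde_cutoff=0.95)
        n_up = len(up & set(bound))
        n_down = len(down & set(bound))
        assert n_up + n_down == 40
        assert stats.binomtest(n_up, 40, 0.5).pvalue > 0.01
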