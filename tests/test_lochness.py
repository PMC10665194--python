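"""Neighbourhood enrichment scores, permutation null, screening, LISI, genes."""

import numpy as np
import pandas as pd
import pytest

from phenoscape import (LochNESS, choose_k, compute_lisi, compute_lochness,
                        lochness_deviance, lochness_gene_assoc, lochness_null,
                        screen_distributions, simulate_expression)
from phenoscape.qc import compute_size_factors
from oracles import brute_lochness


def _cohort_arrays(ds):
    return (ds.embeddings["pca"],
            (ds.cells["genotype"] == "mut").to_numpy(),
            ds.cells["embryo_id"].to_numpy())


class TestChooseK:
    @pytest.mark.parametrize("n,k", [(100, 5), (1000, 16), (4, 1), (64, 4)])
    def test_scaling(self, n, k):
        assert choose_k(n) == k

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            choose_k(3)


class TestScores:
    def test_twelve_cell_line_matches_oracle(self):
        """1-D toy: coordinates 0..11, alternating genotypes, 3 embryos."""
        coords = np.arange(12, dtype=float)[:, None]
        genotype = np.tile([True, False], 6)
        embryo = np.repeat(["e1", "e2", "e3"], 4)
        res = compute_lochness(coords, genotype, embryo, k=3)
        expected = brute_lochness(coords, genotype, embryo, 3)
        assert np.array_equal(res.scores, expected)

    def test_definitional_values(self):
        """Neighbourhood fraction at m/N scores 0; all-mutant scores 1 at 50%."""
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(40, 2))
        genotype = np.arange(40) % 2 == 0          # m/N = 0.5
        embryo = np.where(np.arange(40) % 4 < 2, "e1", "e2")
        res = compute_lochness(coords, genotype, embryo, k=4)
        # scores live on the lattice (c/k)/(m/N)-1
        lattice = (np.arange(5) / 4) / 0.5 - 1
        assert np.all(np.isin(np.round(res.scores, 9), np.round(lattice, 9)))
        assert res.mut_fraction == 0.5

    def test_bounds_and_minus_one_iff_no_mutant_neighbours(self, mixture_cohort):
        coords, genotype, embryo = _cohort_arrays(mixture_cohort)
        est = LochNESS().fit(coords, genotype, embryo)
        assert est.scores_.min() >= -1
        assert est.scores_.max() <= 1 / est.mut_fraction_ - 1 + 1e-12
        none_mut = genotype[est.neighbor_idx_].sum(axis=1) == 0
        assert np.array_equal(est.scores_ == -1, none_mut)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(120, 2))
        genotype = rng.random(120) < 0.4
        embryo = rng.choice(["a", "b", "c"], 120)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        a = compute_lochness(coords, genotype, embryo, k=5).scores
        b = compute_lochness(coords @ R.T, genotype, embryo, k=5).scores
        assert np.array_equal(a, b)

    def test_overlarge_embryo_rejected(self):
        coords = np.random.default_rng(1).normal(size=(30, 2))
        embryo = np.array(["big"] * 28 + ["small"] * 2)
        genotype = np.arange(30) % 2 == 0
        with pytest.raises(ValueError, match="N - k"):
            compute_lochness(coords, genotype, embryo, k=5)

    def test_single_genotype_rejected(self):
        coords = np.zeros((10, 2))
        with pytest.raises(ValueError, match="mutant"):
            compute_lochness(coords, np.ones(10, bool),
                             np.repeat(["a", "b"], 5))


class TestPermutationNull:
    def test_grand_mean_centred_at_zero(self, exchangeable_cohort):
        coords, genotype, embryo = _cohort_arrays(exchangeable_cohort)
        perms = lochness_null(coords, genotype, embryo, n_permutations=60,
                              seed=0)
        perm_means = perms.mean(axis=0)
        mc_se = perm_means.std(ddof=1) / np.sqrt(len(perm_means))
        assert abs(perm_means.mean()) < 3 * mc_se + 1e-12

    def test_permutations_preserve_m_exactly(self, exchangeable_cohort):
        coords, genotype, embryo = _cohort_arrays(exchangeable_cohort)
        est = LochNESS(n_permutations=5, random_state=1).fit(
            coords, genotype, embryo)
        # max score bound implies the same m in every permutation
        upper = 1 / est.mut_fraction_ - 1
        assert np.all(est.perm_scores_ <= upper + 1e-12)
        # mean of scores over all cells is a deterministic function of m
        expected_mean = est.scores_.mean()
        for r in range(5):
            counts = np.rint((est.perm_scores_[:, r] + 1)
                             * est.mut_fraction_ * est.k_)
            assert counts.sum() % 1 == 0

    def test_fixed_seed_bit_identical(self, exchangeable_cohort):
        coords, genotype, embryo = _cohort_arrays(exchangeable_cohort)
        a = lochness_null(coords, genotype, embryo, n_permutations=10, seed=7)
        b = lochness_null(coords, genotype, embryo, n_permutations=10, seed=7)
        assert np.array_equal(a, b)

    def test_tail_calibration_under_null(self, exchangeable_cohort):
        """~5% of observed scores exceed the permutation 95th percentile."""
        coords, genotype, embryo = _cohort_arrays(exchangeable_cohort)
        est = LochNESS(n_permutations=100, random_state=3).fit(
            coords, genotype, embryo)
        q95 = np.quantile(est.perm_scores_, 0.95)
        frac = (est.scores_ > q95).mean()
        assert 0.02 <= frac <= 0.09


class TestDeviance:
    def test_zero_when_observed_equals_permutations(self):
        obs = np.array([0.3, -0.2, 0.1])
        perms = np.tile(obs[:, None], (1, 4))
        assert lochness_deviance(obs, perms) == 0.0

    def test_hand_arithmetic(self):
        assert lochness_deviance(np.array([1.0, 1.0]),
                                 np.array([[0.0], [0.0]])) == pytest.approx(1.0)

    def test_enriched_cohort_larger_deviance(self, mixture_cohort,
                                             exchangeable_cohort):
        wins = 0
        for seed in range(5):
            devs = []
            for ds in (mixture_cohort, exchangeable_cohort):
                coords, genotype, embryo = _cohort_arrays(ds)
                est = LochNESS(n_permutations=20, random_state=seed).fit(
                    coords, genotype, embryo)
                devs.append(est.deviance_)
            wins += devs[0] > devs[1]
        assert wins == 5


class TestScreening:
    def test_enriched_component_ranks_first(self, mixture_cohort):
        coords, genotype, embryo = _cohort_arrays(mixture_cohort)
        est = LochNESS(n_permutations=50, random_state=2).fit(
            coords, genotype, embryo)
        table = screen_distributions(
            est.result(mixture_cohort.cells["sub_trajectory"].to_numpy()))
        assert table.loc[0, "group"] == "component_0"
        assert len(table) == 3

    def test_null_ks_within_permutation_envelope(self, exchangeable_cohort):
        """Exchangeable cohorts stay inside the permutation KS envelope."""
        from scipy import stats
        coords, genotype, embryo = _cohort_arrays(exchangeable_cohort)
        est = LochNESS(n_permutations=50, random_state=4).fit(
            coords, genotype, embryo)
        labels = exchangeable_cohort.cells["sub_trajectory"].to_numpy()
        table = screen_distributions(est.result(labels)).set_index("group")
        exceed = 0
        for g in np.unique(labels):
            members = labels == g
            perm = est.perm_scores_[members]
            null_ks = [
                stats.ks_2samp(perm[:, r],
                               np.delete(perm, r, axis=1).ravel()).statistic
                for r in range(20)]
            exceed += table.loc[g, "ks_statistic"] > np.quantile(null_ks, 0.95)
        assert exceed <= 1    # Monte-Carlo slack on a 5% event over 3 groups

    def test_small_groups_flagged(self, exchangeable_cohort):
        coords, genotype, embryo = _cohort_arrays(exchangeable_cohort)
        est = LochNESS(n_permutations=5, random_state=0).fit(
            coords, genotype, embryo)
        labels = np.array(["tiny"] * 10 + ["rest"] * (len(genotype) - 10))
        table = screen_distributions(est.result(labels))
        assert bool(table.set_index("group").loc["tiny", "low_confidence"])


class TestGeneAssociation:
    def test_bh_hand_computation(self):
        """p = (0.01, 0.02, 0.03, 0.04) all adjust to 0.04."""
        from statsmodels.stats.multitest import multipletests
        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(q, 0.04)

    def test_linked_genes_recovered(self, mixture_cohort):
        cov = np.tanh(mixture_cohort.embeddings["pca"][:, 0] / 4 - 0.5)
        linked = {g: 1.0 for g in range(10)}
        ds = simulate_expression(mixture_cohort, n_genes=150,
                                 linked_genes=linked, seed=6, covariate=cov)
        sf = compute_size_factors(
            np.maximum(ds.cells["umi_count"].to_numpy(float), 1.0))
        res = lochness_gene_assoc(ds.counts, cov, sf.to_numpy())
        hits = res[(res.q_value < 0.05) & (res.beta > 0)]["gene_index"]
        sens = np.isin(list(linked), hits).mean()
        false = np.setdiff1d(hits, list(linked))
        assert sens >= 0.9
        assert len(false) <= max(1, 0.05 * len(hits))

    def test_null_genes_uniform_pvalues(self, exchangeable_cohort):
        from scipy import stats
        rng = np.random.default_rng(9)
        cov = rng.normal(size=exchangeable_cohort.n_cells)
        ds = simulate_expression(exchangeable_cohort, n_genes=300,
                                 linked_genes={}, seed=10, covariate=cov)
        sf = compute_size_factors(
            np.maximum(ds.cells["umi_count"].to_numpy(float), 1.0))
        res = lochness_gene_assoc(ds.counts, cov, sf.to_numpy())
        pv = res.loc[res.tested, "p_value"].to_numpy()
        assert stats.kstest(pv, "uniform").pvalue > 0.01

    def test_zero_count_genes_untested(self, exchangeable_cohort):
        ds = simulate_expression(
            exchangeable_cohort, n_genes=50, linked_genes={}, seed=11,
            covariate=np.zeros(exchangeable_cohort.n_cells))
        ds.counts[7] = 0
        ds.counts.eliminate_zeros()
        sf = np.ones(ds.n_cells)
        res = lochness_gene_assoc(ds.counts,
                                  np.zeros(ds.n_cells) + 0.1 * np.arange(
                                      ds.n_cells) / ds.n_cells, sf)
        assert not bool(res.loc[7, "tested"])


class TestLISI:
    def test_perplexity_formula(self):
        # N=300 -> perplexity 5, K=15 (exercised via separated blobs below)
        assert int(np.floor(0.5 * np.sqrt(300 / 3))) == 5

    def test_mixed_vs_separated(self):
        rng = np.random.default_rng(12)
        mixed = rng.normal(size=(2000, 2))
        labels = np.arange(2000) % 2
        lisi_mixed = compute_lisi(mixed, labels)
        sep = np.vstack([rng.normal(size=(1000, 2)),
                         rng.normal(loc=50.0, size=(1000, 2))])
        sep_labels = np.repeat([0, 1], 1000)
        lisi_sep = compute_lisi(sep, sep_labels)
        assert np.median(lisi_mixed) > 1.8
        assert np.median(lisi_sep) < 1.1

    def test_anticorrelates_with_abs_lochness(self):
        """On separated data, unmixed (low-LISI) areas carry extreme scores."""
        from scipy.stats import spearmanr
        rng = np.random.default_rng(17)
        n_mixed, n_pure = 800, 200
        coords = np.vstack([
            rng.normal(size=(n_mixed, 2)),                  # mixed blob
            rng.normal(loc=(25.0, 0.0), size=(n_pure, 2)),  # pure mutant
            rng.normal(loc=(0.0, 25.0), size=(n_pure, 2)),  # pure wild type
        ])
        genotype = np.concatenate([
            rng.random(n_mixed) < 0.5,
            np.ones(n_pure, dtype=bool),
            np.zeros(n_pure, dtype=bool),
        ])
        embryo = np.where(genotype,
                          rng.choice(["m1", "m2", "m3", "m4"], len(genotype)),
                          rng.choice(["w1", "w2", "w3", "w4"], len(genotype)))
        scores = compute_lochness(coords, genotype, embryo).scores
        lisi = compute_lisi(coords, genotype.astype(int))
        rho = spearmanr(lisi, np.abs(scores)).statistic
        assert rho < -0.5

    def test_tiny_dataset_clamps_perplexity(self):
        with pytest.warns(UserWarning, match="clamp"):
            out = compute_lisi(np.random.default_rng(0).normal(size=(8, 2)),
                               np.arange(8) % 2)
        assert np.all((out >= 1.0) & (out <= 2.0 + 1e-9))


class TestSecondaryModes:
    def test_embryo_level_permutation_null(self, exchangeable_cohort):
        coords = exchangeable_cohort.embeddings["pca"]
        genotype = (exchangeable_cohort.cells["genotype"] == "mut").to_numpy()
        embryo = exchangeable_cohort.cells["embryo_id"].to_numpy()
        est = LochNESS(n_permutations=30, permutation_unit="embryo",
                       random_state=0).fit(coords, genotype, embryo)
        # block permutations still centre near zero on exchangeable data
        assert abs(est.perm_scores_.mean()) < 0.05
        with pytest.raises(ValueError, match="constant within"):
            bad = genotype.copy()
            bad[0] = ~bad[0]
            LochNESS(n_permutations=2, permutation_unit="embryo").fit(
                coords, bad, embryo)

    def test_sorted_and_raw_deviance_variants(self):
        obs = np.array([1.0, -1.0, 0.0, 0.5])
        perms = np.array([[0.0], [0.0], [0.0], [0.0]])
        paired = lochness_deviance(obs, perms)
        srt = lochness_deviance(obs, perms, pairing="sorted")
        raw = lochness_deviance(obs, perms, normalize=False)
        assert srt == pytest.approx(paired)       # permuted scores constant
        assert raw == pytest.approx(paired * 2.0)  # sqrt(n_cells) = 2
        # sorting removes location information: a sign flip changes the
        # per-cell pairing but not the sorted distribution
        obs2 = np.array([1.0, -1.0])
        perms2 = np.array([[-1.0], [1.0]])
        assert lochness_deviance(obs2, perms2) > 0
        assert lochness_deviance(obs2, perms2, pairing="sorted") == 0.0
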