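import numpy as np
import pandas as pd
import pytest

from lpeval.effects import (
    backsolve_effects,
    leave_out_validate,
    permutation_select,
    predict_mbv,
)
from lpeval.errors import ConfigurationError, LpevalError
from lpeval.gblup import MixedModelData, build_G, fit_blup, reml, stabilize_G
from lpeval.simdata import SimConfig, simulate_individuals, simulate_panel
from lpeval.types import GenotypeMatrix


def make_gm(genotypes, animals=None, pos=None):
    g = np.atleast_2d(np.asarray(genotypes, dtype=np.int8))
    n_a, n_v = g.shape
    animals = animals if animals is not None else [f"a{i}" for i in range(n_a)]
    pos = pos if pos is not None else np.arange(1, n_v + 1) * 10
    variants = pd.DataFrame({"chrom": "1", "pos": pos, "ref": "A", "alt": "C"})
    return GenotypeMatrix(g, np.array(animals, dtype=object), variants)


def hwe_genotypes(rng, n, v, p_low=0.15, p_high=0.85):
    p = rng.uniform(p_low, p_high, size=v)
    g = (rng.random((n, v)) < p).astype(np.int8) + (rng.random((n, v)) < p).astype(np.int8)
    return make_gm(g), p


class TestBacksolve:
    def test_identity_design(self):
        # centered M = I, k = 1, G = I: alpha equals u
        m = make_gm([[2, 1], [1, 2]])
        eff = backsolve_effects(m, np.array([1.0, -1.0]), freqs=np.array([0.5, 0.5]),
                                stabilized=False)
        assert np.allclose(eff.alpha, [1.0, -1.0], atol=1e-10)

    def test_two_by_two_hand_inversion(self):
        # centered M = ((1,1),(1,-1)), MM' = 2I, u = (2,0) -> alpha = (1,1)
        m = make_gm([[2, 2], [2, 0]])
        eff = backsolve_effects(m, np.array([2.0, 0.0]), freqs=np.array([0.5, 0.5]),
                                stabilized=False)
        assert np.allclose(eff.alpha, [1.0, 1.0], atol=1e-10)

    def test_exact_mode_matches_default_on_full_rank(self, rng):
        gm, p = hwe_genotypes(rng, 12, 60)
        u = rng.normal(size=12)
        a = backsolve_effects(gm, u, freqs=p, stabilized=False)
        b = backsolve_effects(gm, u, freqs=p, exact=True)
        assert np.allclose(a.alpha, b.alpha, atol=1e-8)

    def test_round_trip_identity(self, rng):
        # external freqs keep centered M full row rank -> M_c alpha == u
        gm, p = hwe_genotypes(rng, 20, 100)
        u = rng.normal(size=20)
        eff = backsolve_effects(gm, u, freqs=p, stabilized=False)
        z = gm.genotypes - 2 * p
        assert np.max(np.abs(z @ eff.alpha - u)) < 1e-6

    def test_length_mismatch(self, rng):
        gm, p = hwe_genotypes(rng, 5, 10)
        with pytest.raises(LpevalError):
            backsolve_effects(gm, np.zeros(4))


class TestPredictMbv:
    def test_training_animals_recover_u(self, rng):
        gm, p = hwe_genotypes(rng, 20, 100)
        u = rng.normal(size=20)
        eff = backsolve_effects(gm, u, freqs=p, stabilized=False)
        mbv = predict_mbv(gm, eff)
        assert np.allclose(mbv.table["mbv"].to_numpy(), u, atol=1e-6)

    def test_all_het_at_half_freq_is_zero(self):
        m_train = make_gm([[0, 2, 0], [2, 0, 2], [1, 1, 1], [1, 1, 1]])
        eff = backsolve_effects(m_train, np.array([1.0, -1.0, 0.3, -0.3]),
                                freqs=np.array([0.5, 0.5, 0.5]))
        target = make_gm([[1, 1, 1]], animals=["het"])
        mbv = predict_mbv(target, eff)
        assert mbv.table["mbv"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_row_duplicates_mbv(self, rng):
        gm, p = hwe_genotypes(rng, 10, 40)
        eff = backsolve_effects(gm, rng.normal(size=10), freqs=p)
        doubled = make_gm(np.vstack([gm.genotypes, gm.genotypes[:1]]),
                          animals=[f"a{i}" for i in range(10)] + ["dup"])
        mbv = predict_mbv(doubled, eff).table
        assert mbv["mbv"].iloc[10] == mbv["mbv"].iloc[0]

    def test_missing_effect_variants_dropped_with_warning(self, rng):
        gm, p = hwe_genotypes(rng, 10, 40)
        eff = backsolve_effects(gm, rng.normal(size=10), freqs=p)
        target = gm.subset(variant_idx=np.arange(30))  # 75% of effect variants
        with pytest.warns(UserWarning, match="dropped 10"):
            predict_mbv(target, eff)

    def test_under_half_present_rejected(self, rng):
        gm, p = hwe_genotypes(rng, 10, 40)
        eff = backsolve_effects(gm, rng.normal(size=10), freqs=p)
        target = gm.subset(variant_idx=np.arange(10))
        with pytest.raises(LpevalError, match="effect variants"):
            predict_mbv(target, eff)


class TestPermutationSelect:
    def test_same_seed_identical(self, rng):
        gm, _ = hwe_genotypes(rng, 60, 80)
        y = rng.normal(size=60)
        X = np.ones((60, 1))
        a = permutation_select(gm, y, X, 0.5, 0.5, n_perm=50, n_keep=8, seed=4)
        b = permutation_select(gm, y, X, 0.5, 0.5, n_perm=50, n_keep=8, seed=4)
        assert np.array_equal(a, b)

    def test_invariant_to_phenotype_scaling(self, rng):
        gm, _ = hwe_genotypes(rng, 60, 80)
        y = rng.normal(size=60)
        X = np.ones((60, 1))
        a = permutation_select(gm, y, X, 0.5, 0.5, n_perm=50, n_keep=8, seed=4)
        b = permutation_select(gm, 3.0 * y, X, 0.5, 0.5, n_perm=50, n_keep=8, seed=4)
        assert np.array_equal(a, b)

    def test_single_qtl_detected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            gm, p = hwe_genotypes(rng, 150, 100)
            qtl = 37
            g_q = gm.genotypes[:, qtl].astype(float)
            u = g_q - g_q.mean()
            u *= np.sqrt(0.3 / np.var(u))
            y = u + rng.normal(0, np.sqrt(0.7), 150)
            sel = permutation_select(gm, y, np.ones((150, 1)), 0.3, 0.7,
                                     n_perm=100, n_keep=10, seed=seed)
            hits += qtl in sel
        assert hits >= 18

    def test_n_keep_too_large(self, rng):
        gm, _ = hwe_genotypes(rng, 10, 5)
        with pytest.raises(ConfigurationError):
            permutation_select(gm, np.zeros(10), np.ones((10, 1)), 1, 1,
                               n_perm=10, n_keep=6)


def _sim_validation_world(seed, n_per_gen=40, v=200, h2=0.6):
    cfg = SimConfig(
        n_panel_haplotypes=80, n_variants=v, chromosome_length=2_000_000,
        n_target_animals=n_per_gen, pedigree_depth=3, n_qtl=40, h2_true=h2,
        recomb_rate=1e-6, seed=seed,
    )
    panel = simulate_panel(cfg)
    pedigree, truth = simulate_individuals(panel, cfg)
    from lpeval.simdata import simulate_phenotypes

    phenos = simulate_phenotypes(truth, cfg)
    return cfg, pedigree, truth, phenos


class TestLeaveOutValidate:
    def run_grid(self, seed, sources=None, variant_sets=None, h2=0.6):
        cfg, pedigree, truth, phenos = _sim_validation_world(seed, h2=h2)
        targets = truth.target_ids()
        gm = truth.true_genotypes
        target_rows = np.flatnonzero(truth.is_target)
        holdout_gm = gm.subset(animal_idx=target_rows)
        sources = sources or {"array": holdout_gm, "copy": holdout_gm}
        variant_sets = variant_sets or {"all": np.arange(gm.n_variants)}
        grid = leave_out_validate(
            gm, phenos.table, ["cg1"], pedigree, targets, variant_sets, sources,
            variances=(phenos.sigma_g2, phenos.sigma_e2),
        )
        return grid, truth, targets

    def test_identical_sources_identical_correlations(self):
        grid, _, _ = self.run_grid(0)
        a = grid[grid["source"] == "array"].set_index("reference")["r"]
        b = grid[grid["source"] == "copy"].set_index("reference")["r"]
        assert np.allclose(a, b)

    def test_high_signal_mbv_tracks_true_bv(self):
        cfg, pedigree, truth, phenos = _sim_validation_world(5, n_per_gen=60, h2=0.9)
        targets = truth.target_ids()
        gm = truth.true_genotypes
        target_rows = np.flatnonzero(truth.is_target)
        variant_sets = {"qtl": truth.qtl_indices}
        train_idx = np.flatnonzero(~truth.is_target)
        m_train = gm.subset(animal_idx=train_idx, variant_idx=truth.qtl_indices)
        rel = build_G(m_train)
        data = MixedModelData(
            y=phenos.table["y"].to_numpy()[train_idx],
            X=np.ones((train_idx.size, 1)),
            Z=np.eye(train_idx.size),
            K=stabilize_G(rel.G),
            sigma_g2=phenos.sigma_g2,
            sigma_e2=phenos.sigma_e2,
        )
        _, u_train = fit_blup(data)
        eff = backsolve_effects(m_train, u_train)
        mbv = predict_mbv(gm.subset(animal_idx=target_rows, variant_idx=truth.qtl_indices), eff)
        r = np.corrcoef(mbv.table["mbv"], truth.true_breeding_values[target_rows])[0, 1]
        assert r > 0.8

    def test_gebv_correlation_beats_pedigree_ebv(self):
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            grid, _, _ = self.run_grid(100 + seed, h2=0.6)
            sub = grid[grid["source"] == "array"].set_index("reference")["r"]
            wins += sub["gebv"] >= sub["pedigree_ebv"]
        assert wins >= 0.8 * n_seeds

    def test_se_formula(self):
        grid, _, _ = self.run_grid(1)
        row = grid.iloc[0]
        assert row["se"] == pytest.approx(
            np.sqrt((1 - row["r"] ** 2) / (row["n"] - 2))
        )
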