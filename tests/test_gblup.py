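import numpy as np
import pandas as pd
import pytest

from _oracles import gls_blup, kinship_A
from conftest import random_pedigree
from lpeval.errors import LpevalError, PedigreeError
from lpeval.gblup import (
    MixedModelData,
    build_A,
    build_G,
    fit_blup,
    project_pwg,
    reml,
    stabilize_G,
)
from lpeval.types import GenotypeMatrix


def ped(rows):
    return pd.DataFrame(rows, columns=["animal", "sire", "dam"])


class TestBuildA:
    def test_trio(self):
        A, ids = build_A(ped([("s", "0", "0"), ("d", "0", "0"), ("o", "s", "d")]))
        i = {a: k for k, a in enumerate(ids)}
        assert A[i["s"], i["o"]] == 0.5
        assert A[i["o"], i["o"]] == 1.0
        assert A[i["s"], i["d"]] == 0.0

    def test_full_sibs(self):
        A, ids = build_A(
            ped([("s", "0", "0"), ("d", "0", "0"), ("o1", "s", "d"), ("o2", "s", "d")])
        )
        i = {a: k for k, a in enumerate(ids)}
        assert A[i["o1"], i["o2"]] == 0.5

    def test_inbred_offspring_of_half_sibs(self):
        # half-sib parents (a = 0.25) -> offspring diagonal 1.125
        rows = [
            ("gs", "0", "0"),
            ("gd1", "0", "0"),
            ("gd2", "0", "0"),
            ("p1", "gs", "gd1"),
            ("p2", "gs", "gd2"),
            ("o", "p1", "p2"),
        ]
        A, ids = build_A(ped(rows))
        i = {a: k for k, a in enumerate(ids)}
        assert A[i["p1"], i["p2"]] == 0.25
        assert A[i["o"], i["o"]] == 1.125

    def test_matches_recursive_kinship_oracle(self, rng):
        pedigree = random_pedigree(rng, n=50, n_founders=8)
        A, ids = build_A(pedigree)
        A_oracle, ids_oracle = kinship_A(pedigree)
        assert np.array_equal(ids, ids_oracle)
        assert np.max(np.abs(A - A_oracle)) < 1e-12

    def test_out_of_order_pedigree_handled(self):
        A, ids = build_A(ped([("o", "s", "d"), ("s", "0", "0"), ("d", "0", "0")]))
        i = {a: k for k, a in enumerate(ids)}
        assert A[i["s"], i["o"]] == 0.5

    def test_cycle_detected(self):
        with pytest.raises(PedigreeError, match="cycle"):
            build_A(ped([("a", "b", "0"), ("b", "a", "0")]))


class TestBuildG:
    def test_single_variant_hand_case(self):
        gm = np.array([[0], [1], [2]], dtype=np.int8)
        variants = pd.DataFrame({"chrom": "1", "pos": [10], "ref": "A", "alt": "C"})
        g = GenotypeMatrix(gm, np.array(["a", "b", "c"], dtype=object), variants)
        rel = build_G(g)
        # p = 0.5, centered (-1, 0, 1), divisor 0.5
        assert rel.divisor == pytest.approx(0.5)
        assert rel.G[0, 0] == pytest.approx(2.0)
        assert rel.G[2, 2] == pytest.approx(2.0)
        assert rel.G[0, 2] == pytest.approx(-2.0)

    def test_identical_animals_constant_G(self, rng):
        row = rng.integers(0, 3, size=20)
        g = np.tile(row, (5, 1)).astype(np.int8)
        rel = build_G(g)
        assert np.allclose(rel.G, rel.G[0, 0])

    def test_hwe_mean_diagonal_near_one(self, rng):
        n, v = 200, 5000
        p = rng.uniform(0.1, 0.9, size=v)
        g = (rng.random((n, v)) < p).astype(np.int8) + (rng.random((n, v)) < p).astype(np.int8)
        rel = build_G(g, freqs=p)
        assert 0.9 <= np.mean(np.diag(rel.G)) <= 1.1

    def test_monomorphic_rejected(self):
        with pytest.raises(LpevalError, match="monomorphic"):
            build_G(np.zeros((4, 3), dtype=np.int8))

    def test_missing_imputed_and_counted(self, rng):
        g = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
        g[0, 0] = -1
        rel = build_G(g)
        assert rel.n_missing_imputed == 1

    def test_too_much_missingness_rejected(self, rng):
        g = rng.integers(0, 3, size=(4, 20)).astype(np.int8)
        g[0, :10] = -1
        with pytest.raises(LpevalError, match="missing"):
            build_G(g)


class TestStabilizeG:
    def test_identity_fixed_point(self):
        assert np.allclose(stabilize_G(np.eye(4)), np.eye(4))

    def test_entrywise_coefficients(self):
        g = np.diag([2.0, 2.0])
        assert stabilize_G(g)[0, 0] == pytest.approx(1.99)

    def test_singular_becomes_invertible(self, rng):
        row = rng.integers(0, 3, size=40)
        g = np.tile(row, (6, 1)).astype(np.int8)
        rel = build_G(g)  # duplicate animals: singular
        gstar = stabilize_G(rel.G)
        assert np.linalg.eigvalsh(gstar).min() > 1e-6


class TestFitBlup:
    def test_two_animal_worked_example(self):
        data = MixedModelData(
            y=[10.0, 12.0], X=np.ones((2, 1)), Z=np.eye(2), K=np.eye(2),
            sigma_g2=1.0, sigma_e2=1.0,
        )
        beta, bv = fit_blup(data)
        assert beta[0] == pytest.approx(11.0, abs=1e-12)
        assert bv.values == pytest.approx([-0.5, 0.5], abs=1e-12)

    def test_shrinkage_limit(self, rng):
        n = 10
        data = MixedModelData(
            y=rng.normal(size=n), X=np.ones((n, 1)), Z=np.eye(n), K=np.eye(n),
            sigma_g2=1e-9, sigma_e2=1.0,
        )
        _, bv = fit_blup(data)
        assert np.max(np.abs(bv.values)) < 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_gls_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, q = 15, 20  # animals in K without records get predictions too
        ped_df = random_pedigree(rng, n=q, n_founders=6)
        K, _ = build_A(ped_df)
        Z = np.zeros((n, q))
        Z[np.arange(n), rng.choice(q, n, replace=False)] = 1.0
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n)])
        y = rng.normal(size=n)
        sg2, se2 = 0.7, 1.3
        beta, bv = fit_blup(MixedModelData(y=y, X=X, Z=Z, K=K, sigma_g2=sg2, sigma_e2=se2))
        beta_o, u_o = gls_blup(y, X, Z, K, sg2, se2)
        assert np.max(np.abs(beta - beta_o)) < 1e-8
        assert np.max(np.abs(bv.values - u_o)) < 1e-8

    def test_singular_K_suggests_stabilizing(self):
        K = np.ones((3, 3))
        data = MixedModelData(y=np.zeros(3), X=np.ones((3, 1)), Z=np.eye(3), K=K,
                              sigma_g2=1.0, sigma_e2=1.0)
        with pytest.raises(LpevalError, match="stabilize_G"):
            fit_blup(data)

    def test_missing_variances_rejected(self):
        data = MixedModelData(y=np.zeros(3), X=np.ones((3, 1)), Z=np.eye(3), K=np.eye(3))
        with pytest.raises(LpevalError, match="variance"):
            fit_blup(data)


class TestReml:
    def test_pure_noise_h2_near_zero(self):
        # null simulation: y is pure noise but the fit uses a structured
        # relationship matrix (with K = I, h2 would be unidentifiable)
        rng = np.random.default_rng(0)
        n = 500
        ped_df = random_pedigree(rng, n=n, n_founders=50)
        K, _ = build_A(ped_df)
        y = rng.normal(size=n)
        est = reml(MixedModelData(y=y, X=np.ones((n, 1)), Z=np.eye(n), K=K))
        assert est.h2 < 0.1

    def test_em_loglik_monotone(self):
        rng = np.random.default_rng(1)
        n = 120
        ped_df = random_pedigree(rng, n=n, n_founders=30)
        K, _ = build_A(ped_df)
        u = np.linalg.cholesky(K + 1e-8 * np.eye(n)) @ rng.normal(size=n)
        y = 3.0 + u + rng.normal(size=n)
        est = reml(MixedModelData(y=y, X=np.ones((n, 1)), Z=np.eye(n), K=K),
                   method="em", max_iter=60)
        ll = est.loglik_trace
        assert all(b >= a - 1e-8 * abs(a) for a, b in zip(ll, ll[1:]))

    def test_h2_recovery_with_identity_K(self):
        rng = np.random.default_rng(2)
        n = 400
        u = rng.normal(0, np.sqrt(0.5), n)
        e = rng.normal(0, np.sqrt(0.5), n)
        est = reml(MixedModelData(y=1 + u + e, X=np.ones((n, 1)), Z=np.eye(n), K=np.eye(n)))
        # with K = I, u and e are confounded; only the total is identified
        assert est.sigma_g2 + est.sigma_e2 == pytest.approx(np.var(u + e), rel=0.2)

    def test_pedigree_h2_recovery_single(self):
        rng = np.random.default_rng(3)
        n = 300
        ped_df = random_pedigree(rng, n=n, n_founders=40)
        K, _ = build_A(ped_df)
        u = np.linalg.cholesky(K + 1e-10 * np.eye(n)) @ rng.normal(0, np.sqrt(0.5), n)
        y = 2.0 + u + rng.normal(0, np.sqrt(0.5), n)
        est = reml(MixedModelData(y=y, X=np.ones((n, 1)), Z=np.eye(n), K=K), method="ai")
        assert est.converged
        assert 0.3 < est.h2 < 0.7
        assert np.isfinite(est.se_h2)


class TestProjectPwg:
    def test_linear_growth(self):
        ages = np.array([210.0, 300.0, 400.0, 500.0])
        assert project_pwg(ages, 50 + 1.0 * ages, wean_age=205) == pytest.approx(1.0)

    def test_exact_quadratic_algebra(self):
        a, b, c, wa = 30.0, 0.8, 0.002, 205.0
        ages = np.array([210.0, 260.0, 330.0, 420.0, 510.0])
        w = a + b * ages + c * ages**2
        expected = b + c * (2 * wa + 160.0)
        assert project_pwg(ages, w, wean_age=wa) == pytest.approx(expected, rel=1e-9)

    def test_noise_within_three_se(self):
        rng = np.random.default_rng(4)
        wa, sigma = 205.0, 2.0
        ages = np.linspace(210, 540, 10)
        w_true = 40 + 0.9 * ages + 0.001 * ages**2
        noiseless = project_pwg(ages, w_true, wean_age=wa)
        noisy = project_pwg(ages, w_true + rng.normal(0, sigma, 10), wean_age=wa)
        X = np.column_stack([np.ones(10), ages, ages**2])
        contrast = np.array([0.0, 1.0, 2 * wa + 160.0]) / 1.0
        se = sigma * np.sqrt(contrast @ np.linalg.inv(X.T @ X) @ contrast)
        assert abs(noisy - noiseless) < 3 * se

    def test_too_few_records(self):
        with pytest.raises(LpevalError):
            project_pwg([200, 300], [200, 300], 205)

    def test_degenerate_ages(self):
        with pytest.raises(LpevalError, match="degenerate"):
            project_pwg([300, 300, 300], [1.0, 2.0, 3.0], 205)


def test_pedigree_and_genomic_h2_agree(small_world):
    """Same simulated data analysed with A and with G* recovers similar h2."""
    from lpeval.effects import _design_from_factors

    truth = small_world["truth"]
    phenos = small_world["phenotypes"]
    y = phenos.table["y"].to_numpy()
    X = _design_from_factors(phenos.table, ["cg1"])
    n = len(y)
    A, ids = build_A(small_world["pedigree"])
    est_a = reml(MixedModelData(y=y, X=X, Z=np.eye(n), K=A))
    gstar = stabilize_G(build_G(truth.true_genotypes).G)
    est_g = reml(MixedModelData(y=y, X=X, Z=np.eye(n), K=gstar))
    assert abs(est_a.h2 - est_g.h2) < 0.35  # loose: tiny n, different information
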