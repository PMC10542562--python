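"""Association stage units: MAF filter, LD pruning, GRM, MLM, permutations, jitter."""

import numpy as np
import pytest
from scipy import stats

from killerome.assoc import (
    AssocConfig,
    MLMEngine,
    compute_grm,
    filter_maf,
    jitter_replicates,
    jitter_robustness,
    ld_prune,
    mlm_assoc,
    permutation_threshold,
    sparsify_grm,
)
from killerome.simulate import SimConfig, simulate_population
from killerome.types import GRM, GenotypeMatrix


def _gm(dosages, ids=None):
    d = np.asarray(dosages)
    return GenotypeMatrix(
        strain_ids=[f"s{i}" for i in range(d.shape[0])],
        site_ids=ids or [f"x{j}" for j in range(d.shape[1])],
        dosages=d,
    )


class TestMafFilter:
    def test_monomorphic_removed_and_exact_boundary_retained(self):
        # site0 monomorphic; site1 has MAF exactly 0.05 (1 het / 10 diploids)
        d = np.zeros((10, 3), dtype=int)
        d[0, 1] = 1
        d[:5, 2] = 2  # MAF 0.5
        out = filter_maf(_gm(d), 0.05)
        assert out.site_ids == ["x1", "x2"]

    def test_common_sites_all_retained(self):
        d = np.tile([0, 1, 2, 1], (5, 1)).T
        assert filter_maf(_gm(d), 0.05).n_sites == 5


class TestLdPrune:
    def test_duplicate_site_pruned_to_one(self, rng):
        x = rng.integers(0, 3, size=50)
        out = ld_prune(_gm(np.column_stack([x, x])))
        assert len(out) == 1

    def test_independent_sites_both_kept(self, rng):
        d = rng.integers(0, 3, size=(200, 2))
        assert len(ld_prune(_gm(d))) == 2

    def test_matches_brute_force_oracle_on_small_panels(self, rng):
        def oracle(X, maf, r2_max):
            # naive greedy keep in (MAF desc, index asc) order, per-pair corrcoef
            kept = []
            for i in sorted(range(X.shape[1]), key=lambda i: (-maf[i], i)):
                ok = True
                for j in kept:
                    with np.errstate(invalid="ignore"):
                        r = np.corrcoef(X[:, i], X[:, j])[0, 1]
                    if not np.isnan(r) and r**2 > r2_max:
                        ok = False
                        break
                if ok:
                    kept.append(i)
            return sorted(kept)

        for _ in range(200):
            m = int(rng.integers(2, 7))
            base = rng.integers(0, 3, size=(30, m))
            # duplicate some columns to force conflicts
            for j in range(m):
                if rng.random() < 0.4 and j > 0:
                    base[:, j] = base[:, j - 1]
            gm = _gm(base)
            got = ld_prune(gm, r2_max=0.5, window=10, step=1).tolist()
            exp = oracle(gm.imputed(), gm.minor_allele_freqs(), 0.5)
            assert got == exp


class TestGrm:
    def test_identical_strains_offdiagonal_equals_diagonal(self):
        d = np.array([[0, 2, 1, 1], [0, 2, 1, 1]])
        with pytest.warns(UserWarning, match="monomorphic"):
            K = compute_grm(_gm(d)).values
        assert K[0, 1] == pytest.approx(K[0, 0])

    def test_matches_direct_formula_oracle(self, rng):
        d = rng.integers(0, 3, size=(8, 12))
        gm = _gm(d)
        K = compute_grm(gm).values
        X = gm.imputed()
        p = X.mean(0) / 2
        keep = (p > 0) & (p < 1)
        X, p = X[:, keep], p[keep]
        m = X.shape[1]
        expected = np.zeros((8, 8))
        for j in range(8):
            for k in range(8):
                expected[j, k] = np.mean(
                    (X[j] - 2 * p) * (X[k] - 2 * p) / (2 * p * (1 - p))
                )
        assert np.allclose(K, expected, atol=1e-12)
        assert m <= 12

    def test_hwe_cohort_calibration(self):
        cfg = SimConfig(n_strains=200, n_sites=5000, n_subpops=1, fst=0.0, seed=7)
        gm, _, _ = simulate_population(cfg)
        K = compute_grm(gm).values
        assert np.diag(K).mean() == pytest.approx(1.0, abs=0.05)
        off = K[~np.eye(200, dtype=bool)]
        assert abs(off.mean()) < 0.02

    def test_positive_semidefinite(self, rng):
        gm = _gm(rng.integers(0, 3, size=(30, 100)))
        K = compute_grm(gm).values
        assert np.linalg.eigvalsh(K).min() > -1e-8

    def test_monomorphic_site_warned_and_excluded(self):
        d = np.array([[0, 1], [0, 2], [0, 0]])
        with pytest.warns(UserWarning, match="monomorphic"):
            compute_grm(_gm(d))


class TestSparsify:
    def test_thresholding_rules(self):
        K = np.array([[1.0, 0.04, 0.06], [0.04, 1.0, -0.3], [0.06, -0.3, 1.0]])
        S = sparsify_grm(GRM(["a", "b", "c"], K), 0.05).values
        assert S[0, 1] == 0.0 and S[0, 2] == 0.06 and S[1, 2] == 0.0
        assert (np.diag(S) == 1.0).all()
        assert (S == S.T).all()

    def test_identity_unchanged(self):
        S = sparsify_grm(GRM(["a", "b"], np.eye(2)), 0.99).values
        assert (S == np.eye(2)).all()


class TestMlm:
    def test_reduces_to_ols_score_test_under_identity_grm(self, rng):
        n = 80
        gm = _gm(rng.integers(0, 3, size=(n, 20)))
        y = rng.standard_normal(n)
        res = mlm_assoc(gm, y, GRM(gm.strain_ids, np.eye(n)))
        # oracle: score chi2 = n * r^2 with MLE variance, chi2_1 p
        X = gm.imputed()
        for j in range(20):
            r = np.corrcoef(X[:, j], y)[0, 1]
            p_exp = stats.chi2.sf(n * r**2, 1)
            assert res["p_value"][j] == pytest.approx(p_exp, abs=1e-10)

    def test_perfect_association_underflows(self, rng):
        n = 100
        gm = _gm(rng.integers(0, 3, size=(n, 5)))
        x = gm.imputed()[:, 2]
        y = (x - x.mean()) / x.std()
        res = mlm_assoc(gm, y, GRM(gm.strain_ids, np.eye(n)))
        assert res["p_value"][2] < 1e-12

    def test_he_components_zero_for_identity_grm(self, rng):
        engine = MLMEngine(np.eye(50))
        sg, se = engine.he_components(rng.standard_normal((50, 3)))
        assert (sg == 0).all() and (se > 0).all()


class TestPermutationThreshold:
    def test_single_site_threshold_near_alpha(self):
        cfg = SimConfig(n_strains=200, n_sites=1, n_subpops=1, fst=0.0,
                        heritability_background=0.0, seed=7)
        gm, _, _ = simulate_population(cfg)
        rng = np.random.default_rng(0)
        y = rng.standard_normal(200)
        thr = permutation_threshold(gm, y, GRM(gm.strain_ids, np.eye(200)), AssocConfig(seed=5))
        assert thr == pytest.approx(0.05, abs=0.015)

    def test_fixed_seed_reproducible(self, rng):
        gm = _gm(rng.integers(0, 3, size=(60, 30)))
        y = rng.standard_normal(60)
        grm = GRM(gm.strain_ids, np.eye(60))
        cfg = AssocConfig(n_perm=200, seed=11)
        assert permutation_threshold(gm, y, grm, cfg) == permutation_threshold(gm, y, grm, cfg)

    def test_few_permutations_warn(self, rng):
        gm = _gm(rng.integers(0, 3, size=(30, 5)))
        y = rng.standard_normal(30)
        with pytest.warns(UserWarning, match="permutation"):
            permutation_threshold(
                gm, y, GRM(gm.strain_ids, np.eye(30)), AssocConfig(n_perm=10, seed=1)
            )


class TestJitter:
    def test_zero_sd_fractions_are_degenerate(self, rng):
        gm = _gm(rng.integers(0, 3, size=(50, 10)))
        y = rng.standard_normal(50)
        out = jitter_robustness(
            gm, y, GRM(gm.strain_ids, np.eye(50)), threshold=0.05,
            cfg=AssocConfig(jitter_sd=1e-300, n_jitter=20, seed=3),
        )
        assert set(out["jitter_fraction"]).issubset({0.0, 1.0})

    def test_between_class_order_preserved_within_class_randomized(self):
        """Jitter sd 0.25 on the 0-3 scale: per adjacent-class pair the
        inversion probability is < 0.3%, so with one strain per class more
        than 99% of replicates preserve all between-class orderings, while
        within-class orderings are fully randomized."""
        y = np.array([0.0, 1.0, 2.0, 3.0])
        Y = jitter_replicates(y, AssocConfig(n_jitter=20000, seed=13))
        ordered = (np.diff(Y, axis=0) > 0).all(axis=0)
        assert ordered.mean() > 0.99
        # two strains in the same class: order is a fair coin under jitter
        Y2 = jitter_replicates(np.array([1.0, 1.0]), AssocConfig(n_jitter=20000, seed=13))
        flip = (Y2[0] > Y2[1]).mean()
        assert 0.45 < flip < 0.55
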