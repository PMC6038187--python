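"""Tests of phenotype BLUPs, the relationship matrix, spectral REML and the
across/within heritability partition."""

import numpy as np
import pandas as pd
import pytest

import structgs as s

from conftest import make_matrix


def pheno_frame(values, reps=None):
    """Long table from a (genotypes x replicates) array."""
    values = np.asarray(values, dtype=float)
    G, R = values.shape
    return s.PhenotypeTable(
        pd.DataFrame(
            {
                "genotype_id": np.repeat([f"g{i:03d}" for i in range(G)], R),
                "replicate_id": np.tile(np.arange(1, R + 1), G),
                "trait": "t",
                "value": values.ravel(),
            }
        )
    )


def dense_restricted_ll(y, A, delta):
    """Independent dense-matrix restricted log-likelihood (X = intercept)."""
    n = len(y)
    X = np.ones((n, 1))
    V = A + delta * np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    s2 = float(r.T @ Vi @ r) / (n - 1)
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XtViX)
    return -0.5 * ((n - 1) * np.log(s2) + ldV + ldX + (n - 1)), s2, float(beta[0])


def henderson_gebv(y, A, delta):
    """GEBV from Henderson's mixed-model equations at a given variance ratio."""
    n = len(y)
    X = np.ones((n, 1))
    Ai = np.linalg.inv(A + 1e-10 * np.eye(n))
    lhs = np.block([[X.T @ X, X.T], [X, np.eye(n) + delta * Ai]])
    rhs = np.concatenate([X.T @ y, y])
    sol = np.linalg.solve(lhs, rhs)
    return sol[1:]


class TestStandardize:
    def test_unit_moments_and_idempotence(self):
        p = pheno_frame(np.array([[1.0, 2.0], [3.0, 1.0], [2.0, 3.0]]))
        q = s.standardize_trait(p, "t")
        vals = q.trait_records("t")["value"]
        assert vals.mean() == pytest.approx(0.0, abs=1e-12)
        assert vals.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        q2 = s.standardize_trait(q, "t")
        assert np.allclose(q2.trait_records("t")["value"], vals, atol=1e-12)

    def test_back_transform_round_trip(self):
        raw = np.array([[1.0, 2.0], [5.0, 4.0], [2.0, 3.0]])
        p = pheno_frame(raw)
        q = s.standardize_trait(p, "t")
        restored = s.back_transform(q, "t", q.trait_records("t")["value"].to_numpy())
        assert np.allclose(restored, raw.ravel(), atol=1e-12)

    def test_zero_variance_rejected(self):
        p = pheno_frame(np.full((3, 2), 7.0))
        with pytest.raises(ValueError, match="zero variance"):
            s.standardize_trait(p, "t")


class TestGenotypeBlups:
    def test_balanced_case_matches_anova_moments(self):
        """Balanced one-way REML equals the closed-form ANOVA estimators."""
        rng = np.random.default_rng(31)
        G, R = 120, 2
        gv = rng.normal(0, 1, G)
        vals = gv[:, None] + rng.normal(0, 1, (G, R))
        b = s.fit_genotype_blups(pheno_frame(vals), "t")
        msb = R * np.var(vals.mean(axis=1), ddof=1)
        msw = np.mean(np.var(vals, axis=1, ddof=1))
        assert b.sigma2_e == pytest.approx(msw, abs=1e-6)
        assert b.sigma2_g == pytest.approx((msb - msw) / R, abs=1e-4)
        assert b.repeatability == b.sigma2_g / (b.sigma2_g + b.sigma2_e / b.n_reps_mean)

    def test_repeatability_near_formula_value(self):
        """sigma2_G = sigma2_e = 1 with 2 replicates forces H2 near 2/3."""
        rng = np.random.default_rng(32)
        G, R = 400, 2
        vals = rng.normal(0, 1, G)[:, None] + rng.normal(0, 1, (G, R))
        b = s.fit_genotype_blups(pheno_frame(vals), "t")
        assert b.repeatability == pytest.approx(1 / 1.5, abs=0.05)

    def test_zero_noise_limit(self):
        rng = np.random.default_rng(33)
        gv = rng.normal(0, 1, 50)
        vals = np.repeat(gv[:, None], 3, axis=1)
        b = s.fit_genotype_blups(pheno_frame(vals), "t")
        assert b.repeatability == 1.0
        assert np.allclose(np.sort(b.values.to_numpy()), np.sort(gv))

    def test_single_replicate_everywhere_rejected(self):
        p = pheno_frame(np.array([[1.0], [2.0], [3.0]]))
        with pytest.raises(ValueError, match="replicate"):
            s.fit_genotype_blups(p, "t")

    def test_repeatability_monotone_in_replicates(self):
        b = s.TraitBLUPs("t", pd.Series(dtype=float), 1.0, 1.0, 1.0, 0.0)
        h = [
            s.TraitBLUPs("t", pd.Series(dtype=float), 1.0, 1.0, float(n), 0.0).repeatability
            for n in (1, 2, 4, 8)
        ]
        assert all(np.diff(h) > 0)


class TestGRM:
    def test_three_by_two_toy_hand_computed(self):
        dosage = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]])
        g = make_matrix(dosage)
        K = s.compute_grm(g)
        # p = (0.5, 0.5); W columns centered by 1; denom = 2*(0.25+0.25) = 1
        W = dosage - 1.0
        expect = W @ W.T / 1.0
        assert np.allclose(K.A, expect, atol=1e-12)
        assert K.denominator == pytest.approx(1.0)

    def test_duplicated_individuals_share_entries(self):
        rng = np.random.default_rng(41)
        row = rng.binomial(2, 0.5, 200).astype(float)
        other = rng.binomial(2, 0.5, (3, 200)).astype(float)
        g = make_matrix(np.vstack([row, row, other]))
        K = s.compute_grm(g)
        assert K.A[0, 1] == pytest.approx(K.A[0, 0], abs=1e-12)
        assert K.A[0, 0] == pytest.approx(K.A[1, 1], abs=1e-12)

    def test_hardy_weinberg_expectation(self):
        rng = np.random.default_rng(42)
        m = 5000
        p = rng.uniform(0.1, 0.9, m)
        dosage = rng.binomial(2, p, size=(60, m)).astype(float)
        K = s.compute_grm(make_matrix(dosage))
        assert np.mean(np.diag(K.A)) == pytest.approx(1.0, abs=0.05)
        off = K.A[~np.eye(60, dtype=bool)]
        assert abs(off.mean()) < 0.05

    def test_monomorphic_sites_ignored(self):
        rng = np.random.default_rng(43)
        dosage = rng.binomial(2, 0.5, size=(10, 20)).astype(float)
        padded = np.column_stack([dosage, np.zeros((10, 5)), np.full((10, 5), 2.0)])
        K1 = s.compute_grm(make_matrix(dosage))
        K2 = s.compute_grm(make_matrix(padded))
        assert np.allclose(K1.A, K2.A, atol=1e-12)

    def test_all_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            s.compute_grm(make_matrix(np.zeros((5, 4))))

    def test_eigendecomposition_contract(self, two_pop_panel):
        g, _ = two_pop_panel
        K = s.compute_grm(g)
        U, lam = K.eig()
        n = K.n
        assert U.shape == (n, n - 1) and len(lam) == n - 1
        assert np.all(np.diff(lam) <= 1e-9) and lam[-1] >= 0
        assert np.allclose(U.T @ U, np.eye(n - 1), atol=1e-8)
        # dropped direction is the centering null vector
        assert np.allclose(K.A @ np.ones(n), 0.0, atol=1e-8)


class TestSpectralREML:
    def test_identity_kinship_equals_ridge_shrinkage(self):
        rng = np.random.default_rng(51)
        n = 40
        y = rng.normal(size=n)
        K = s.KinshipMatrix(np.eye(n), [f"i{i}" for i in range(n)], 1.0)
        fit = s.reml_single_kernel(y, K)
        expect = (y - y.mean()) / (1.0 + fit.delta)
        assert np.allclose(fit.u, expect, atol=1e-8)

    def test_matches_dense_oracle_on_small_instances(self):
        """Spectral REML agrees with a dense-matrix likelihood search and
        Henderson-equation GEBVs on n <= 30 instances."""
        from scipy.optimize import minimize_scalar

        rng = np.random.default_rng(52)
        for trial in range(6):
            n, m = 25, 80
            dosage = rng.binomial(2, rng.uniform(0.2, 0.8, m), size=(n, m)).astype(float)
            K = s.compute_grm(make_matrix(dosage))
            u = np.linalg.cholesky(K.A + 1e-6 * np.eye(n)) @ rng.normal(size=n)
            y = 2.0 + u + rng.normal(scale=0.7, size=n)
            fit = s.reml_single_kernel(y, K)
            res = minimize_scalar(
                lambda t: -dense_restricted_ll(y, K.A, np.exp(t))[0],
                bounds=(np.log(1e-5), np.log(1e5)),
                method="bounded",
            )
            ll_o, _, _ = dense_restricted_ll(y, K.A, np.exp(res.x))
            assert abs(fit.loglik - ll_o) < 1e-6
            gebv_o = henderson_gebv(y, K.A, fit.delta)
            assert np.max(np.abs(fit.u - gebv_o)) < 1e-6

    def test_interpolation_limit_without_noise(self):
        rng = np.random.default_rng(53)
        n, m = 30, 300
        dosage = rng.binomial(2, rng.uniform(0.2, 0.8, m), size=(n, m)).astype(float)
        K = s.compute_grm(make_matrix(dosage))
        y = np.linalg.cholesky(K.A + 1e-8 * np.eye(n)) @ rng.normal(size=n)
        fit = s.reml_single_kernel(y, K)
        assert np.allclose(fit.beta[0] + fit.u, y, atol=1e-3)

    def test_predicts_unphenotyped_through_kinship(self):
        """Unphenotyped clones of training individuals inherit their genetic
        prediction through the kinship rows."""
        rng = np.random.default_rng(54)
        n, m = 60, 400
        base = rng.binomial(2, rng.uniform(0.2, 0.8, m), size=(n, m)).astype(float)
        clones = base[:20]                       # rows 60..79 duplicate rows 0..19
        g = make_matrix(np.vstack([base, clones]))
        K = s.compute_grm(g)
        u = np.linalg.cholesky(K.A + 1e-6 * np.eye(K.n)) @ rng.normal(size=K.n)
        y = u + rng.normal(scale=0.3, size=K.n)
        y_masked = y.copy()
        y_masked[n:] = np.nan                    # clones unphenotyped
        fit = s.reml_single_kernel(y_masked, K)
        r = np.corrcoef(u[n:], fit.u[n:])[0, 1]
        assert r > 0.8

    def test_permutation_invariance(self):
        rng = np.random.default_rng(55)
        n, m = 30, 100
        dosage = rng.binomial(2, 0.5, size=(n, m)).astype(float)
        y = rng.normal(size=n)
        perm = rng.permutation(n)
        K1 = s.compute_grm(make_matrix(dosage))
        K2 = s.compute_grm(make_matrix(dosage[perm]))
        f1 = s.reml_single_kernel(y, K1)
        f2 = s.reml_single_kernel(y[perm], K2)
        assert f1.sigma2_g == pytest.approx(f2.sigma2_g, abs=1e-10)
        assert f1.sigma2_e == pytest.approx(f2.sigma2_e, abs=1e-10)
        assert np.allclose(f1.u[perm], f2.u, atol=1e-8)


class TestHeritabilityPartition:
    def test_additivity_identities_exact(self, structured_trait_panel):
        g, labels, y, _ = structured_trait_panel
        K = s.compute_grm(g)
        for est in ("blup", "posterior"):
            part = s.partition_heritability(y, K, d=3, estimator=est)
            assert part.sigma2_gA + part.sigma2_gW == pytest.approx(part.sigma2, abs=1e-14)
            assert part.h2_gA + part.h2_gW == pytest.approx(part.h2_g, abs=1e-14)
            assert 0 <= part.h2_gA <= 1 and 0 <= part.h2_gW <= 1 and 0 <= part.h2_g <= 1

    def test_d_zero_degenerate_config(self, structured_trait_panel):
        g, labels, y, _ = structured_trait_panel
        K = s.compute_grm(g)
        part = s.partition_heritability(y, K, d=0)
        assert part.sigma2_gA == 0.0 and part.h2_gA == 0.0
        assert part.h2_gW == pytest.approx(part.h2_g, abs=1e-14)

    def test_recovers_balanced_architecture(self):
        """At a well-powered design (n = 400, m = 2000) both components of a
        (0.25, 0.25) architecture are recovered to within ~0.1."""
        design = s.PopulationDesign(
            ["P1", "P2", "P3"], {"P1": 134, "P2": 133, "P3": 133}, {p: 0.15 for p in ("P1", "P2", "P3")}
        )
        layout = s.GenomeLayout.regular(2, 1000, copy_prob=None)
        g, labels = s.simulate_structured_genotypes(design, layout, seed=65)
        arch = s.TraitArchitecture(n_qtl=200, h2_within=0.25, h2_across=0.25, n_reps=1)
        ds = s.simulate_trait(g, labels, arch, seed=66)
        y = (
            ds.phenotypes.data.groupby("genotype_id", sort=False)["value"].mean().loc[g.samples].to_numpy()
        )
        part = s.partition_heritability(y, s.compute_grm(g), d=3)
        assert part.h2_gA == pytest.approx(0.25, abs=0.12)
        assert part.h2_gW == pytest.approx(0.25, abs=0.12)

    def test_single_population_has_little_across_component(self):
        design = s.PopulationDesign(["A"], {"A": 200}, {"A": 0.0})
        layout = s.GenomeLayout.regular(1, 1000, copy_prob=None)
        g, labels = s.simulate_structured_genotypes(design, layout, seed=61)
        arch = s.TraitArchitecture(n_qtl=100, h2_within=0.5, h2_across=0.0, n_reps=1)
        ds = s.simulate_trait(g, labels, arch, seed=62)
        y = (
            ds.phenotypes.data.groupby("genotype_id", sort=False)["value"].mean().loc[g.samples].to_numpy()
        )
        part = s.partition_heritability(y, s.compute_grm(g), d=3)
        assert part.h2_gA < 0.1
        assert part.h2_gW > 0.2

    def test_across_dominated_regime(self):
        """Strong population means with no within-population QTL put > 80% of
        genomic heritability on the leading components."""
        design = s.PopulationDesign(
            ["P1", "P2", "P3"], {p: 70 for p in ("P1", "P2", "P3")}, {p: 0.2 for p in ("P1", "P2", "P3")}
        )
        layout = s.GenomeLayout.regular(1, 900, copy_prob=None)
        g, labels = s.simulate_structured_genotypes(design, layout, seed=63)
        arch = s.TraitArchitecture(n_qtl=100, h2_within=0.0, h2_across=0.55, n_reps=4)
        ds = s.simulate_trait(g, labels, arch, seed=64)
        y = (
            ds.phenotypes.data.groupby("genotype_id", sort=False)["value"].mean().loc[g.samples].to_numpy()
        )
        part = s.partition_heritability(y, s.compute_grm(g), d=3)
        assert part.fraction_across > 0.8

    def test_invalid_d_rejected(self, structured_trait_panel):
        g, labels, y, _ = structured_trait_panel
        K = s.compute_grm(g)
        with pytest.raises(ValueError):
            s.partition_heritability(y, K, d=K.n - 1)
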