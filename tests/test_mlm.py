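import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pxgs
from pxgs.mlm import UsageError, _Component, _reml

from _oracles import balanced_oneway_reml
from conftest import toy_pedigree


def _oneway_data(seed=0, s=12, m=15, s2b=0.6, s2w=1.0):
    """Balanced one-way layout: s groups of m, group ids double as kernel ids."""
    rng = np.random.default_rng(seed)
    groups = np.repeat([f"g{k}" for k in range(s)], m)
    b = rng.normal(0, np.sqrt(s2b), s)
    y = 3.0 + np.repeat(b, m) + rng.normal(0, np.sqrt(s2w), s * m)
    pheno = pd.DataFrame({"id": groups, "site": "S1", "Y": y})
    kernel = pxgs.RelationshipMatrix([f"g{k}" for k in range(s)], np.eye(s),
                                     source="pedigree")
    return pheno, kernel, y, groups


class TestRemlCore:
    def test_identity_kernel_reproduces_oneway_reml(self):
        """With an identity kernel over group labels and a single site, the
        fit is the classical balanced one-way random-effects model and must
        match its closed-form REML estimators."""
        pheno, kernel, y, groups = _oneway_data()
        spec = pxgs.ModelSpec(trait="Y", kernel_additive=kernel,
                              random_terms=("additive",))
        fit = pxgs.fit_model(pheno, spec, compute_blups=False)
        s2b, s2w = balanced_oneway_reml(y, groups)
        assert fit.vc.sigma2_a == pytest.approx(s2b, abs=1e-6)
        assert fit.vc.mean_residual == pytest.approx(s2w, abs=1e-6)

    def test_balanced_halfsib_matches_closed_form(self):
        """Animal model on a balanced paternal half-sib design equals the
        sire-model ANOVA/REML estimators re-expressed on the additive scale."""
        rng = np.random.default_rng(3)
        s, m = 15, 20
        sires = [f"S{i}" for i in range(s)]
        rows = [{"id": x, "mother": None, "father": None} for x in sires]
        off_ids = []
        for i in range(s):
            for j in range(m):
                oid = f"O{i}_{j}"
                off_ids.append(oid)
                rows.append({"id": oid, "mother": None, "father": sires[i]})
        ped = pd.DataFrame(rows)
        A = pxgs.compute_A_additive(ped)
        K = A.submatrix(off_ids).values
        L = np.linalg.cholesky(K + 1e-10 * np.eye(s * m))
        y = 5.0 + np.sqrt(0.4) * (L @ rng.standard_normal(s * m)) \
            + rng.standard_normal(s * m)
        pheno = pd.DataFrame({"id": off_ids, "site": "S1", "HT": y})
        spec = pxgs.ModelSpec(trait="HT", kernel_additive=A,
                              random_terms=("additive",))
        fit = pxgs.fit_model(pheno, spec, compute_blups=False)
        groups = np.repeat(np.arange(s), m)
        s2b, s2w = balanced_oneway_reml(y, groups)
        a_closed, e_closed = 4.0 * s2b, s2w - 3.0 * s2b
        assert fit.vc.sigma2_a == pytest.approx(a_closed, abs=1e-6)
        assert fit.vc.mean_residual == pytest.approx(e_closed, abs=1e-6)

    def test_em_iterations_never_decrease_loglik(self):
        pheno, kernel, y, groups = _oneway_data(seed=5)
        n = len(y)
        Z = (pheno["id"].to_numpy()[:, None] == kernel.ids[None, :]).astype(float)
        comps = [_Component("additive", Z @ Z.T, em_dim=kernel.n),
                 _Component("resid", np.eye(n), em_dim=n)]
        X = np.ones((n, 1))
        res = _reml(y, X, comps, n_em=10_000, max_iter=60)  # pure EM
        trace = np.asarray(res["ll_trace"])
        assert (np.diff(trace) >= -1e-8).all()

    def test_blups_satisfy_mixed_model_equations(self):
        """At convergence, V (P y) must equal the fixed-effect residual
        y - X beta; this is the mixed-model identity the BLUPs derive from."""
        pheno, kernel, y, groups = _oneway_data(seed=6)
        n = len(y)
        Z = (pheno["id"].to_numpy()[:, None] == kernel.ids[None, :]).astype(float)
        comps = [_Component("additive", Z @ Z.T, em_dim=kernel.n),
                 _Component("resid", np.eye(n), em_dim=n)]
        X = np.ones((n, 1))
        res = _reml(y, X, comps)
        V = res["theta"]["additive"] * (Z @ Z.T) + res["theta"]["resid"] * np.eye(n)
        lhs = V @ res["Py"]
        rhs = y - X @ res["beta"]
        assert np.linalg.norm(lhs - rhs) < 1e-8 * np.linalg.norm(y)

    def test_constrained_components_held_fixed(self):
        pheno, kernel, *_ = _oneway_data(seed=7)
        spec = pxgs.ModelSpec(trait="Y", kernel_additive=kernel,
                              random_terms=("additive",),
                              constrained_components={"additive": 0.123})
        fit = pxgs.fit_model(pheno, spec, compute_blups=False)
        assert fit.vc.sigma2_a == 0.123

    def test_missing_phenotypes_dropped(self):
        pheno, kernel, *_ = _oneway_data(seed=8)
        pheno.loc[:9, "Y"] = np.nan
        spec = pxgs.ModelSpec(trait="Y", kernel_additive=kernel,
                              random_terms=("additive",))
        fit = pxgs.fit_model(pheno, spec, compute_blups=False)
        assert fit.n_obs == len(pheno) - 10

    def test_spec_validation(self):
        kernel = pxgs.RelationshipMatrix(["a"], np.eye(1))
        with pytest.raises(UsageError):
            pxgs.ModelSpec(trait="Y", kernel_additive=kernel,
                           random_terms=("rep_in_site",))  # additive missing
        with pytest.raises(UsageError):
            pxgs.ModelSpec(trait="Y", kernel_additive=kernel,
                           random_terms=("additive", "site_x_dominance"))


class TestLRT:
    def _fits(self, seed=11, sa=0.4, fam=18):
        cfg = pxgs.SimConfig(n_females=8, n_males=6, n_snps=600,
                             offspring_per_family=fam, n_sites=3,
                             reps_per_site=3, sets_per_rep=2, seed=seed,
                             maternal_mislabel_rate=0, dual_genotype_mother_fraction=0,
                             contamination_rate=0, selfing_rate=0)
        founders = pxgs.simulate_founders(cfg)
        geno, truth = pxgs.simulate_polycross(founders, cfg)
        design = pxgs.assign_field_design(geno.sample_ids, cfg)
        traits = [pxgs.TraitConfig(name="T", sigma2_a=0.3, sigma2_sa=sa,
                                   sigma2_e_by_site=0.5, site_means=[1., 2., 3.])]
        pheno, _ = pxgs.simulate_phenotypes(truth, geno, design, traits, seed=seed)
        G = pxgs.compute_G_additive(geno)
        full = pxgs.fit_model(pheno, pxgs.ModelSpec(
            trait="T", kernel_additive=G,
            random_terms=("additive", "site_x_additive")), compute_blups=False)
        reduced = pxgs.fit_model(pheno, pxgs.ModelSpec(
            trait="T", kernel_additive=G, random_terms=("additive",)),
            compute_blups=False)
        return full, reduced

    def test_identical_fits_give_null_result(self):
        full, _ = self._fits()
        res = pxgs.lrt_component(full, full.__class__(**{**full.__dict__}))
        assert res.stat == 0.0 and res.p_value == pytest.approx(1.0)
        assert res.p_value_mixture == pytest.approx(1.0)

    def test_chi_square_quantile(self):
        # a statistic of 3.84 sits at the 5% upper tail of chi-square(1)
        assert stats.chi2.sf(3.84, 1) == pytest.approx(0.050, abs=5e-4)

    def test_strong_interaction_detected(self):
        full, reduced = self._fits(seed=12, sa=1.5, fam=40)
        res = pxgs.lrt_component(full, reduced)
        assert res.df == 1
        assert res.p_value < 0.001
        assert res.p_value_mixture <= res.p_value

    def test_non_nested_rejected(self):
        full, reduced = self._fits(seed=13)
        with pytest.raises(UsageError):
            pxgs.lrt_component(reduced, full)

    def test_null_additive_rejection_rate_at_most_nominal(self):
        """With a true additive variance of zero, the chi-square(1) LRT is
        conservative (boundary null): rejection rate <= 5% nominal."""
        rng = np.random.default_rng(0)
        n, q = 120, 30
        kernel = pxgs.RelationshipMatrix([f"g{k}" for k in range(q)], np.eye(q))
        rejections = 0
        reps = 25
        for r in range(reps):
            ids = np.repeat(kernel.ids, n // q)
            y = rng.normal(0.0, 1.0, n)  # no group signal at all
            pheno = pd.DataFrame({"id": ids, "site": "S1", "Y": y})
            full = pxgs.fit_model(pheno, pxgs.ModelSpec(
                trait="Y", kernel_additive=kernel, random_terms=("additive",)),
                compute_blups=False)
            # the reduced model has no random term besides the residual: use
            # the analytic REML loglik of the fixed-effects-only model
            X = np.ones((n, 1))
            resid = y - y.mean()
            s2 = float(resid @ resid) / (n - 1)
            ll0 = -0.5 * ((n - 1) * np.log(2 * np.pi * s2) + np.log(n) / 1.0
                          + (n - 1))
            stat = max(0.0, 2.0 * (full.loglik_reml - ll0))
            if stats.chi2.sf(stat, 1) < 0.05:
                rejections += 1
        assert rejections / reps <= 0.05 + 1e-9


class TestDerivedQuantities:
    def test_heritability_from_printed_components(self):
        vc = pxgs.VarianceComponents(sigma2_a=1468, sigma2_sa=824,
                                     sigma2_e_by_site={"mean": 8753})
        h2, se = pxgs.heritability(vc)
        assert round(h2, 2) == 0.13
        vc2 = pxgs.VarianceComponents(sigma2_a=0.14, sigma2_sa=0.06,
                                      sigma2_e_by_site={"mean": 0.54})
        assert round(pxgs.heritability(vc2)[0], 2) == 0.19

    def test_broad_sense_reduces_to_narrow_without_dominance(self):
        vc = pxgs.VarianceComponents(sigma2_a=2.0, sigma2_sa=0.0, sigma2_d=0.0,
                                     sigma2_sd=0.0, sigma2_e_by_site={"s": 3.0})
        assert pxgs.heritability(vc, "broad")[0] == pytest.approx(
            pxgs.heritability(vc, "narrow")[0])

    def test_typeb_from_printed_components(self):
        assert round(pxgs.typeB_correlation(pxgs.VarianceComponents(
            sigma2_a=1468, sigma2_sa=824, sigma2_e_by_site={"s": 1}))[0], 2) == 0.64
        assert round(pxgs.typeB_correlation(pxgs.VarianceComponents(
            sigma2_a=58, sigma2_sa=56, sigma2_e_by_site={"s": 1}))[0], 2) == 0.51

    def test_typeb_is_one_without_interaction(self):
        vc = pxgs.VarianceComponents(sigma2_a=5.0, sigma2_sa=0.0,
                                     sigma2_e_by_site={"s": 1.0})
        assert pxgs.typeB_correlation(vc)[0] == pytest.approx(1.0)

    def test_typeb_undefined_when_both_zero(self):
        vc = pxgs.VarianceComponents(sigma2_a=0.0, sigma2_sa=0.0,
                                     sigma2_e_by_site={"s": 1.0})
        assert pxgs.typeB_correlation(vc) == (None, None)

    def test_accuracy_formula_endpoints(self):
        kernel = pxgs.RelationshipMatrix(["a", "b", "c"], np.eye(3))
        spec = pxgs.ModelSpec(trait="Y", kernel_additive=kernel,
                              random_terms=("additive",))
        fit = pxgs.ModelFit(
            spec=spec, vc=pxgs.VarianceComponents(sigma2_a=1.0,
                                                  sigma2_e_by_site={"s": 1.0}),
            loglik_reml=0.0, aic=0.0, fixed_estimates=pd.Series(dtype=float),
            blups={"additive": pd.DataFrame({
                "id": ["a", "b", "c"], "blup": [0.1, 0.2, 0.3],
                "se": [0.0, 1.0, 0.6]})},
            converged=True, n_iter=1, n_obs=3, theta={})
        acc = pxgs.theoretical_accuracy(fit).set_index("id")["accuracy"]
        assert acc["a"] == pytest.approx(1.0)      # SE = 0
        assert acc["b"] == pytest.approx(0.0)      # SE^2 = (1+F) s2a
        assert acc["c"] == pytest.approx(0.8)      # sqrt(1 - 0.36)
        assert pxgs.theoretical_accuracy(fit)["inbreeding_F"].eq(0).all()


class TestAdjustedPhenotypes:
    def test_site_means_removed_exactly(self):
        pheno = pd.DataFrame({
            "id": [f"i{k}" for k in range(30)],
            "site": ["S1"] * 15 + ["S2"] * 15,
            "Y": [10.0] * 15 + [20.0] * 15,
        })
        kernel = pxgs.RelationshipMatrix(pheno["id"].tolist(), np.eye(30))
        spec = pxgs.ModelSpec(trait="Y", kernel_additive=kernel,
                              random_terms=("additive",))
        ystar = pxgs.adjusted_phenotypes(pheno, spec)
        np.testing.assert_allclose(ystar.to_numpy(), 0.0, atol=1e-10)

    def test_variance_never_increases(self, clean_trial):
        pheno, G = clean_trial["pheno"], clean_trial["G"]
        spec = pxgs.ModelSpec(trait="HT", kernel_additive=G)
        ystar = pxgs.adjusted_phenotypes(pheno, spec)
        assert ystar.var() <= pheno["HT"].var() + 1e-12

    def test_adjusted_correlation_tracks_generating_composite(self):
        """For two traits sharing genetics, the correlation of adjusted
        phenotypes approximates the correlation of their genetic+residual
        composites."""
        cfg = pxgs.SimConfig(n_females=8, n_males=6, n_snps=500,
                             offspring_per_family=25, n_sites=2,
                             reps_per_site=3, sets_per_rep=2, seed=19,
                             maternal_mislabel_rate=0, dual_genotype_mother_fraction=0,
                             contamination_rate=0, selfing_rate=0)
        founders = pxgs.simulate_founders(cfg)
        geno, truth = pxgs.simulate_polycross(founders, cfg)
        design = pxgs.assign_field_design(geno.sample_ids, cfg)
        traits = [pxgs.TraitConfig(name="T1", sigma2_a=0.5, sigma2_e_by_site=0.5,
                                   sigma2_rep=0.3, site_means=[1.0, 2.0])]
        pheno, truth = pxgs.simulate_phenotypes(truth, geno, design, traits, seed=19)
        rng = np.random.default_rng(19)
        bv = truth.true_breeding_values.set_index("id")["T1"].loc[pheno["id"]]
        pheno["T2"] = 5.0 + bv.to_numpy() + rng.normal(0, 0.7, len(pheno))
        G = pxgs.compute_G_additive(geno)
        s1 = pxgs.ModelSpec(trait="T1", kernel_additive=G,
                            random_terms=("rep_in_site", "additive"))
        s2 = pxgs.ModelSpec(trait="T2", kernel_additive=G,
                            random_terms=("rep_in_site", "additive"))
        y1, y2 = pxgs.adjusted_phenotypes(pheno, s1), pxgs.adjusted_phenotypes(pheno, s2)
        r_adj = np.corrcoef(y1.to_numpy(), y2.to_numpy())[0, 1]
        # generating composite: shared bv + independent residuals
        comp1 = pheno["T1"] - pheno["site"].map({"S1": 1.0, "S2": 2.0})
        r_true = 0.5 / np.sqrt(1.0 * (0.5 + 0.49))  # cov/sds of composites
        assert abs(r_adj - r_true) < 0.15


class TestBivariateCorrelation:
    def _trial(self, seed):
        cfg = pxgs.SimConfig(n_females=8, n_males=6, n_snps=800,
                             offspring_per_family=20, n_sites=2,
                             reps_per_site=3, sets_per_rep=2, seed=seed,
                             maternal_mislabel_rate=0, dual_genotype_mother_fraction=0,
                             contamination_rate=0, selfing_rate=0)
        founders = pxgs.simulate_founders(cfg)
        geno, truth = pxgs.simulate_polycross(founders, cfg)
        design = pxgs.assign_field_design(geno.sample_ids, cfg)
        traits = [pxgs.TraitConfig(name="T1", sigma2_a=0.5, sigma2_e_by_site=0.4),
                  pxgs.TraitConfig(name="T2", sigma2_a=0.5, sigma2_e_by_site=0.4)]
        pheno, truth = pxgs.simulate_phenotypes(truth, geno, design, traits, seed=seed)
        return pheno, truth, pxgs.compute_G_additive(geno)

    def test_shared_genetics_detected(self):
        pheno, truth, G = self._trial(23)
        rng = np.random.default_rng(23)
        bv = truth.true_breeding_values.set_index("id")["T1"].loc[pheno["id"]]
        pheno["T3"] = bv.to_numpy() + rng.normal(0, 0.5, len(pheno))
        res = pxgs.genetic_correlation_bivariate(pheno, "T1", "T3", G)
        assert res["converged"]
        assert res["r_g"] > 1.0 - 2.0 * max(res["se"], 0.05)
        assert res["significant"]

    def test_sign_flip_gives_minus_one(self):
        pheno, _, G = self._trial(24)
        pheno["T3"] = -pheno["T1"]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = pxgs.genetic_correlation_bivariate(pheno, "T1", "T3", G)
        assert res["r_g"] == pytest.approx(-1.0, abs=1e-6)

    def test_independent_traits_mostly_nonsignificant(self):
        hits = 0
        reps = 6
        for seed in range(30, 30 + reps):
            pheno, _, G = self._trial(seed)
            res = pxgs.genetic_correlation_bivariate(pheno, "T1", "T2", G)
            if res["significant"]:
                hits += 1
        assert hits <= 1  # at most ~1 false positive among 6 null replicates
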