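import numpy as np
import pandas as pd
import pytest

import pxgs


@pytest.fixture(scope="session")
def small_cohort():
    """A small polycross cohort with all error types injected, shared by
    reconstruction-oriented tests."""
    cfg = pxgs.SimConfig(
        n_females=10, n_males=8, n_snps=1200, offspring_per_family=24,
        n_sites=2, reps_per_site=4, sets_per_rep=2, seed=21,
        male_weights=np.arange(1, 9) / 36.0,  # unequal but not extreme
        maternal_mislabel_rate=0.10, dual_genotype_mother_fraction=0.2,
        contamination_rate=0.05, selfing_rate=0.02,
    )
    founders = pxgs.simulate_founders(cfg)
    geno, truth = pxgs.simulate_polycross(founders, cfg)
    allg = pxgs.GenotypeMatrix(
        np.concatenate([founders.genotypes.sample_ids, geno.sample_ids]),
        founders.genotypes.snp_ids.copy(),
        np.vstack([founders.genotypes.dosage, geno.dosage]),
    )
    G = pxgs.compute_G_additive(allg)
    return {"config": cfg, "founders": founders, "geno": geno, "truth": truth,
            "all_geno": allg, "G": G}


@pytest.fixture(scope="session")
def clean_trial():
    """An error-free multi-site trial with phenotypes, for model tests."""
    cfg = pxgs.SimConfig(
        n_females=12, n_males=10, n_snps=1500, offspring_per_family=30,
        n_sites=3, reps_per_site=5, sets_per_rep=2, seed=33,
        maternal_mislabel_rate=0.0, dual_genotype_mother_fraction=0.0,
        contamination_rate=0.0, selfing_rate=0.0,
    )
    founders = pxgs.simulate_founders(cfg)
    geno, truth = pxgs.simulate_polycross(founders, cfg)
    design = pxgs.assign_field_design(geno.sample_ids, cfg)
    traits = [pxgs.TraitConfig(
        name="HT", sigma2_a=0.3, sigma2_sa=0.1, sigma2_rep=0.05, sigma2_set=0.02,
        sigma2_e_by_site=[0.5, 0.6, 0.7], site_means=[10.0, 12.0, 14.0])]
    pheno, truth = pxgs.simulate_phenotypes(truth, geno, design, traits, seed=33)
    G = pxgs.compute_G_additive(geno)
    return {"config": cfg, "founders": founders, "geno": geno, "truth": truth,
            "design": design, "pheno": pheno, "G": G}


def toy_pedigree() -> pd.DataFrame:
    """Three founders, two half-sib offspring sharing the father, one
    full-sib pair, and one selfed offspring."""
    return pd.DataFrame({
        "id":     ["f1", "f2", "f3", "hs1", "hs2", "fs1", "fs2", "s1"],
        "mother": [None, None, None, "f1", "f2", "f1", "f1", "f3"],
        "father": [None, None, None, "f3", "f3", "f3", "f3", "f3"],
    })
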