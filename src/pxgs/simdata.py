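"""Synthetic polycross progeny trials with known ground truth.

Emulates the structure of a conifer polycross breeding trial: a founder
pool of female and male parent trees, offspring produced by pollinating
each female with a mix of all males in unequal proportions, field testing
on several sites in single-tree plots (replicates containing incomplete
blocks/sets), and the bookkeeping errors such trials accumulate —
mislabeled maternal records, mother trees with two possible genotypes,
pollen contamination from outside the male pool, and selfing.

Every generated cohort carries a :class:`TruthBundle` recording the true
and recorded pedigrees, per-offspring status flags, and (after phenotype
simulation) the true breeding and dominance values, so downstream
reconstruction and estimation can be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .relmat import GenotypeMatrix, compute_G_additive, compute_G_dominance


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Polycross trial layout and error rates.

    Defaults mirror the study conditions the generator emulates: 26
    maternal families crossed with a 21-male polymix of unequal
    contributions, ~12% maternal record errors plus 8/26 dual-genotype
    mothers, 5% pollen contamination, occasional selfing, and three test
    sites with single-tree plots in replicates subdivided into sets.
    """

    n_females: int = 26
    n_males: int = 21
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    offspring_per_family: int | list[int] = 58
    male_weights: np.ndarray | None = None  # Dirichlet(alpha) draw if absent
    male_weight_alpha: float = 1.0
    maternal_mislabel_rate: float = 0.12
    dual_genotype_mother_fraction: float = 8 / 26
    contamination_rate: float = 0.05
    selfing_rate: float = 0.01
    n_shared_roles: int = 0  # parents used as both female and male
    n_sites: int = 3
    reps_per_site: int = 10
    sets_per_rep: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        if self.n_females + self.n_males < 2:
            raise ConfigurationError("need at least two founders")
        for name in ("maternal_mislabel_rate", "dual_genotype_mother_fraction",
                     "contamination_rate", "selfing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.n_shared_roles > min(self.n_females, self.n_males):
            raise ConfigurationError("n_shared_roles exceeds available parents")
        if self.male_weights is not None:
            w = np.asarray(self.male_weights, dtype=float)
            if w.shape != (self.n_males,):
                raise ConfigurationError("male_weights length must equal n_males")
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-12:
                raise ConfigurationError("male_weights must be a simplex vector (sum 1)")
            self.male_weights = w

    @property
    def family_sizes(self) -> np.ndarray:
        if np.isscalar(self.offspring_per_family):
            return np.full(self.n_females, int(self.offspring_per_family))
        sizes = np.asarray(self.offspring_per_family, dtype=int)
        if sizes.shape != (self.n_females,):
            raise ConfigurationError("offspring_per_family list length must equal n_females")
        return sizes


@dataclass
class TraitConfig:
    """Variance structure of one simulated trait.

    sigma2_a / sigma2_sa are the additive and site-by-additive variances;
    sigma2_d / sigma2_sd the dominance analogues; sigma2_e_by_site the
    heterogeneous residual variances.  ``lognormal`` traits are simulated
    on the log scale and exponentiated, mimicking right-skewed wood
    chemistry traits.
    """

    name: str
    sigma2_a: float = 1.0
    sigma2_sa: float = 0.0
    sigma2_d: float = 0.0
    sigma2_sd: float = 0.0
    sigma2_e_by_site: float | list[float] = 1.0
    sigma2_rep: float = 0.0
    sigma2_set: float = 0.0
    site_means: list[float] | None = None
    lognormal: bool = False
    covariate_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("sigma2_a", "sigma2_sa", "sigma2_d", "sigma2_sd", "sigma2_rep", "sigma2_set"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if np.any(np.asarray(self.sigma2_e_by_site) < 0):
            raise ConfigurationError("residual variances must be >= 0")

    def residual_by_site(self, n_sites: int) -> np.ndarray:
        e = np.asarray(self.sigma2_e_by_site, dtype=float)
        if e.ndim == 0:
            return np.full(n_sites, float(e))
        if e.shape != (n_sites,):
            raise ConfigurationError("sigma2_e_by_site length must equal n_sites")
        return e


@dataclass
class FounderSet:
    genotypes: GenotypeMatrix
    pedigree: pd.DataFrame
    female_ids: list
    male_ids: list
    allele_freq: np.ndarray


@dataclass
class TruthBundle:
    """Ground truth for one simulated cohort.

    ``status`` holds one label per offspring from {clean,
    mislabeled_mother, dual_genotype, contaminant, self}; the boolean
    columns record each condition independently since they can co-occur
    (the label uses the priority dual_genotype > contaminant > self >
    mislabeled_mother).
    """

    true_pedigree: pd.DataFrame
    recorded_pedigree: pd.DataFrame
    status_flags: pd.DataFrame
    hidden_mothers: dict
    male_weights: np.ndarray
    true_breeding_values: pd.DataFrame | None = None
    true_dominance_values: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        off = self.status_flags["offspring_id"]
        if off.duplicated().any():
            raise ConfigurationError("an offspring appears twice in the truth bundle")


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _hwe_draw(rng: np.random.Generator, p: np.ndarray, n: int) -> np.ndarray:
    """Hardy-Weinberg genotype draws: dosage = sum of two Bernoulli(p) gametes."""
    return (rng.random((n, p.size)) < p).astype(float) + (rng.random((n, p.size)) < p)


def simulate_founders(config: SimConfig) -> FounderSet:
    """Draw an unrelated, non-inbred founder pool.

    Per-SNP allele frequencies are uniform on ``maf_range``; founder
    genotypes are independent Hardy-Weinberg draws.  The last
    ``n_shared_roles`` females also serve as males, shrinking the founder
    census accordingly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    female_ids = [f"F{i + 1:03d}" for i in range(config.n_females)]
    male_only = config.n_males - config.n_shared_roles
    male_ids = [f"M{i + 1:03d}" for i in range(male_only)]
    if config.n_shared_roles:
        male_ids += female_ids[-config.n_shared_roles:]
    founder_ids = female_ids + male_ids[:male_only]
    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_snps)
    dosage = _hwe_draw(rng, p, len(founder_ids))
    snp_ids = np.array([f"snp{j + 1:05d}" for j in range(config.n_snps)], dtype=object)
    g = GenotypeMatrix(np.asarray(founder_ids, dtype=object), snp_ids, dosage)
    ped = pd.DataFrame({"id": founder_ids, "mother": pd.NA, "father": pd.NA})
    return FounderSet(g, ped, female_ids, male_ids, p)


def draw_fathers(config: SimConfig, rng: np.random.Generator, n: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Draw true-father indices for ``n`` offspring of one mother.

    Lightweight sampling of the polycross mating law without genotypes:
    returns (father_index, status) arrays where status 0 = polymix male
    (father_index into the male list), 1 = self, 2 = foreign contaminant
    (father_index = -1 for both non-polymix cases).
    """
    w = config.male_weights
    if w is None:
        w = rng.dirichlet(np.full(config.n_males, config.male_weight_alpha))
    u = rng.random(n)
    status = np.zeros(n, dtype=int)
    status[u < config.selfing_rate] = 1
    status[(u >= config.selfing_rate)
           & (u < config.selfing_rate + config.contamination_rate)] = 2
    idx = rng.choice(config.n_males, size=n, p=np.asarray(w, float))
    idx[status != 0] = -1
    return idx, status


def _gamete(rng: np.random.Generator, dosage_row: np.ndarray) -> np.ndarray:
    """One Mendelian gamete per SNP from a parent dosage row (unlinked loci)."""
    het = dosage_row == 1.0
    allele = (dosage_row == 2.0).astype(float)
    allele[het] = rng.integers(0, 2, size=het.sum()).astype(float)
    return allele


def simulate_polycross(founders: FounderSet, config: SimConfig
                       ) -> tuple[GenotypeMatrix, TruthBundle]:
    """Mate the founder pool and corrupt the records.

    Each offspring's true father is drawn from the (possibly Dirichlet)
    male contribution weights, or is the mother itself with probability
    ``selfing_rate``, or a freshly simulated unrelated foreign parent with
    probability ``contamination_rate``.  Gametes segregate independently
    per SNP.  The recorded pedigree corrupts maternity at
    ``maternal_mislabel_rate``; a chosen fraction of mothers carry a
    second, hidden genotype that truly mothers a Uniform(0.3, 0.7) share
    of their recorded family.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    geno = founders.genotypes
    female_ids, male_ids = founders.female_ids, founders.male_ids
    row = {s: i for i, s in enumerate(geno.sample_ids)}

    # weights drawn once per cohort
    if config.male_weights is not None:
        weights = np.asarray(config.male_weights, float)
    else:
        weights = rng.dirichlet(np.full(config.n_males, config.male_weight_alpha))

    n_dual = int(round(config.dual_genotype_mother_fraction * config.n_females))
    dual_mothers = list(rng.choice(config.n_females, size=n_dual, replace=False)) if n_dual else []
    hidden_geno: dict[str, np.ndarray] = {}
    hidden_share: dict[str, float] = {}
    for fi in dual_mothers:
        mid = female_ids[fi]
        hid = f"{mid}_hidden"
        hidden_geno[hid] = _hwe_draw(rng, founders.allele_freq, 1)[0]
        hidden_share[mid] = rng.uniform(0.3, 0.7)

    sizes = config.family_sizes
    records = []
    dosages = []
    foreign_count = 0
    foreign_geno: dict[str, np.ndarray] = {}
    counter = 0
    for fi, mid in enumerate(female_ids):
        n_off = sizes[fi]
        fathers, fstatus = [], []
        u = rng.random(n_off)
        for k in range(n_off):
            if u[k] < config.selfing_rate:
                fathers.append(mid)
                fstatus.append("self")
            elif u[k] < config.selfing_rate + config.contamination_rate:
                foreign_count += 1
                xid = f"X{foreign_count:03d}"
                foreign_geno[xid] = _hwe_draw(rng, founders.allele_freq, 1)[0]
                fathers.append(xid)
                fstatus.append("contaminant")
            else:
                fathers.append(male_ids[rng.choice(config.n_males, p=weights)])
                fstatus.append("in_mix")
        hid = f"{mid}_hidden"
        is_dual_family = mid in hidden_share
        dual_draw = rng.random(n_off) < hidden_share.get(mid, 0.0)
        for k in range(n_off):
            counter += 1
            oid = f"O{counter:05d}"
            from_hidden = bool(is_dual_family and dual_draw[k])
            true_mother = hid if from_hidden else mid
            father = fathers[k]
            if father == mid and from_hidden:
                father = hid  # a self of the dual mother selfs her true genotype
            mg = hidden_geno[hid] if from_hidden else geno.dosage[row[mid]]
            if father in foreign_geno:
                fg = foreign_geno[father]
            elif father == hid:
                fg = hidden_geno[hid]
            else:
                fg = geno.dosage[row[father]]
            dosages.append(_gamete(rng, mg) + _gamete(rng, fg))
            mislabeled = rng.random() < config.maternal_mislabel_rate
            if mislabeled and config.n_females > 1:
                others = [f for f in female_ids if f != mid]
                recorded_mother = others[rng.integers(len(others))]
            else:
                recorded_mother = mid
            records.append({
                "offspring_id": oid,
                "true_mother": true_mother,
                "true_father": father,
                "recorded_mother": recorded_mother,
                "mislabeled_mother": mislabeled,
                "dual_genotype": from_hidden,
                "contaminant": fstatus[k] == "contaminant",
                "self": fstatus[k] == "self",
                "father_in_mix": fstatus[k] == "in_mix",
            })

    flags = pd.DataFrame(records)

    def _label(r):
        if r["dual_genotype"]:
            return "dual_genotype"
        if r["contaminant"]:
            return "contaminant"
        if r["self"]:
            return "self"
        if r["mislabeled_mother"]:
            return "mislabeled_mother"
        return "clean"

    flags["status"] = flags.apply(_label, axis=1)

    offspring_ids = flags["offspring_id"].to_numpy(object)
    off_geno = GenotypeMatrix(offspring_ids, geno.snp_ids.copy(), np.vstack(dosages))

    true_ped = pd.concat([
        founders.pedigree,
        pd.DataFrame({"id": list(hidden_geno), "mother": pd.NA, "father": pd.NA}),
        pd.DataFrame({"id": list(foreign_geno), "mother": pd.NA, "father": pd.NA}),
        flags.rename(columns={"offspring_id": "id", "true_mother": "mother",
                              "true_father": "father"})[["id", "mother", "father"]],
    ], ignore_index=True)
    recorded_ped = pd.concat([
        founders.pedigree,
        pd.DataFrame({
            "id": flags["offspring_id"],
            "mother": flags["recorded_mother"],
            "father": pd.NA,  # polycross: father unknown a priori
        }),
    ], ignore_index=True)

    truth = TruthBundle(
        true_pedigree=true_ped,
        recorded_pedigree=recorded_ped,
        status_flags=flags,
        hidden_mothers={m: f"{m}_hidden" for m in hidden_share},
        male_weights=weights,
    )
    return off_geno, truth


def assign_field_design(offspring_ids, config: SimConfig, seed: int | None = None
                        ) -> pd.DataFrame:
    """Assign each offspring to one site / replicate / set position.

    Offspring are shuffled and dealt round-robin across sites, then across
    replicates within site and sets within replicate — a single-tree-plot
    layout with incomplete blocks.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.seed if seed is None else seed, 2]))
    ids = np.asarray(offspring_ids, dtype=object)
    perm = rng.permutation(len(ids))
    rows = []
    for k, idx in enumerate(perm):
        site = k % config.n_sites
        within = k // config.n_sites
        rep = within % config.reps_per_site
        setn = (within // config.reps_per_site) % config.sets_per_rep
        rows.append({"id": ids[idx], "site": f"S{site + 1}",
                     "rep": f"R{rep + 1}", "set": f"B{setn + 1}"})
    return pd.DataFrame(rows).sort_values("id", ignore_index=True)


def _mvn_from_kernel(rng, kernel_values: np.ndarray, scale2: float) -> np.ndarray:
    if scale2 == 0.0:
        return np.zeros(kernel_values.shape[0])
    n = kernel_values.shape[0]
    jitter = 1e-8 * float(np.trace(kernel_values)) / n
    chol = np.linalg.cholesky(kernel_values + jitter * np.eye(n))
    return np.sqrt(scale2) * (chol @ rng.standard_normal(n))


def simulate_phenotypes(
    truth: TruthBundle,
    genotypes: GenotypeMatrix,
    design: pd.DataFrame,
    traits: list[TraitConfig],
    seed: int,
    kernel_source: str = "marker",
) -> tuple[pd.DataFrame, TruthBundle]:
    """Simulate phenotypes under the individual-tree model.

    ``y = site mean + rep-in-site + set-in-rep + a + sa + d + sd + e``
    with a and d drawn from the marker-derived true kernels (or the true
    pedigree kernels when ``kernel_source="pedigree"``), sa/sd drawn
    independently per site with within-site covariance proportional to the
    corresponding kernel, and heterogeneous residuals by site.  Lognormal
    traits are exponentiated after simulation on the log scale.  Fills the
    truth bundle's true breeding / dominance value tables.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    ids = design["id"].to_numpy(object)
    if set(ids) - set(genotypes.sample_ids):
        from .relmat import IntegrityError
        raise IntegrityError("design references individuals without genotypes")
    if design["id"].duplicated().any():
        from .relmat import IntegrityError
        raise IntegrityError("each individual must occupy exactly one field position")

    if kernel_source == "marker":
        ksub = genotypes.subset(samples=ids)
        K_a = compute_G_additive(ksub).values
        K_d = compute_G_dominance(ksub).values
    elif kernel_source == "pedigree":
        from .relmat import compute_A_additive, compute_A_dominance
        A = compute_A_additive(truth.true_pedigree)
        K_a = A.submatrix(ids).values
        K_d = compute_A_dominance(truth.true_pedigree, A).submatrix(ids).values
    else:
        raise ConfigurationError(f"unknown kernel_source {kernel_source!r}")

    sites = design["site"].to_numpy(object)
    site_levels = sorted(set(sites))
    rep_labels = (design["site"].astype(str) + ":" + design["rep"].astype(str)).to_numpy(object)
    set_labels = (rep_labels + ":" + design["set"].astype(str))

    pheno = design.copy()
    bv_cols, dv_cols = {}, {}
    cov_values: dict[str, np.ndarray] = {}
    for trait in traits:
        n = len(ids)
        site_means = trait.site_means or [0.0] * len(site_levels)
        if len(site_means) != len(site_levels):
            raise ConfigurationError("site_means length must equal number of sites")
        mu = np.array([site_means[site_levels.index(s)] for s in sites])
        y = mu.copy()
        for labels, v in ((rep_labels, trait.sigma2_rep), (set_labels, trait.sigma2_set)):
            if v > 0:
                levels = sorted(set(labels))
                eff = rng.normal(0.0, np.sqrt(v), size=len(levels))
                y += eff[[levels.index(l) for l in labels]]
        a = _mvn_from_kernel(rng, K_a, trait.sigma2_a)
        d = _mvn_from_kernel(rng, K_d, trait.sigma2_d)
        y += a + d
        sa = np.zeros(n)
        sd = np.zeros(n)
        for s in site_levels:
            at_site = sites == s
            if trait.sigma2_sa > 0:
                sa[at_site] = _mvn_from_kernel(rng, K_a, trait.sigma2_sa)[at_site]
            if trait.sigma2_sd > 0:
                sd[at_site] = _mvn_from_kernel(rng, K_d, trait.sigma2_sd)[at_site]
        y += sa + sd
        evars = trait.residual_by_site(len(site_levels))
        for k, s in enumerate(site_levels):
            at_site = sites == s
            if evars[k] > 0:
                y[at_site] += rng.normal(0.0, np.sqrt(evars[k]), size=at_site.sum())
        for cov, beta in trait.covariate_effects.items():
            if cov not in cov_values:
                cov_values[cov] = rng.standard_normal(n)
            y += beta * cov_values[cov]
        pheno[trait.name] = np.exp(y) if trait.lognormal else y
        bv_cols[trait.name] = a
        dv_cols[trait.name] = d

    for cov, vals in cov_values.items():
        pheno[cov] = vals
    truth.true_breeding_values = pd.DataFrame({"id": ids, **bv_cols})
    truth.true_dominance_values = pd.DataFrame({"id": ids, **dv_cols})
    return pheno, truth


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def write_simulation(outdir, founders: FounderSet, offspring: GenotypeMatrix,
                     truth: TruthBundle, design: pd.DataFrame | None = None,
                     pheno: pd.DataFrame | None = None) -> list:
    """Write a simulated cohort as plain-text files; returns written paths."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    all_geno = GenotypeMatrix(
        np.concatenate([founders.genotypes.sample_ids, offspring.sample_ids]),
        founders.genotypes.snp_ids.copy(),
        np.vstack([founders.genotypes.dosage, offspring.dosage]),
    )
    paths = []

    def _w(name, writer):
        p = out / name
        writer(p)
        paths.append(p)

    _w("genotypes.vcf", all_geno.to_vcf)
    _w("genotypes.tsv", all_geno.to_dosage_tsv)
    _w("pedigree_true.csv", lambda p: truth.true_pedigree.to_csv(p, index=False))
    _w("pedigree_recorded.csv", lambda p: truth.recorded_pedigree.to_csv(p, index=False))
    _w("status_flags.csv", lambda p: truth.status_flags.to_csv(p, index=False))
    if design is not None:
        _w("design.csv", lambda p: design.to_csv(p, index=False))
    if pheno is not None:
        _w("phenotypes.csv", lambda p: pheno.to_csv(p, index=False))
    if truth.true_breeding_values is not None:
        _w("true_breeding_values.csv",
           lambda p: truth.true_breeding_values.to_csv(p, index=False))
    return paths
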