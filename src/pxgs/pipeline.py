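"""End-to-end reproducible pipeline.

Orchestrates simulate → genotype QC → relationship matrices → pedigree
reconstruction → mixed-model fits → selection report as one deterministic
run driven by a single config (YAML file or dict), writing every stage
output plus a manifest with parameters, seed, and file checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mlm, pedrecon, selection, simdata
from .relmat import (GenotypeMatrix, compute_A_additive, compute_A_dominance,
                     compute_G_additive, compute_G_dominance, filter_snps,
                     impute_missing)

logger = logging.getLogger("pxgs")

MODEL_REGISTRY = {
    "ablup-px": {"kernel": "A_PX", "dominance": False},
    "ablup-fs-a": {"kernel": "A_FS", "dominance": False},
    "ablup-fs-ad": {"kernel": "A_FS", "dominance": True},
    "gblup-a": {"kernel": "G", "dominance": False},
    "gblup-ad": {"kernel": "G", "dominance": True},
}


class ConfigurationError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    sim: simdata.SimConfig
    traits: list
    models: list = field(default_factory=lambda: ["gblup-a", "ablup-px"])
    reference_model: str = "gblup-a"
    thresholds: pedrecon.ThresholdConfig = field(default_factory=pedrecon.ThresholdConfig)
    selection_fraction: float = 0.05
    maf_min: float = 0.01
    max_snp_missing: float = 0.20
    max_ind_missing: float = 0.40
    impute_method: str = "mean"
    outdir: str = "pxgs_run"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [m for m in self.models if m not in MODEL_REGISTRY]
        if unknown:
            raise ConfigurationError(
                f"unknown model name(s) {unknown}; known: {sorted(MODEL_REGISTRY)}")
        if self.reference_model not in self.models:
            raise ConfigurationError("reference_model must be among models")
        if not 0 < self.selection_fraction <= 1:
            raise ConfigurationError("selection_fraction must lie in (0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        seed = int(d.get("seed", 0))
        sim = simdata.SimConfig(**{**d.pop("sim", {}), "seed": seed})
        traits = [simdata.TraitConfig(**t) for t in d.pop("traits")]
        th = pedrecon.ThresholdConfig(**d.pop("thresholds", {}))
        return cls(sim=sim, traits=traits, thresholds=th, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to
    ``<outdir>/manifest.json``).  Reruns with the same config and seed
    reproduce byte-identical outputs."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    manifest: dict = {"seed": config.seed, "stages": {}}

    def _finish_stage(stage: str, paths):
        outputs.extend(paths)
        manifest["stages"][stage] = [str(p.relative_to(out)) for p in paths]
        logger.info("stage %s complete (%d files)", stage, len(paths))

    def _fail(stage: str, exc: Exception):
        record = {"stage": stage, "error": type(exc).__name__, "message": str(exc)}
        (out / "error.json").write_text(json.dumps(record, sort_keys=True, indent=1))
        raise StageError(stage, exc) from exc

    # -- simulate -----------------------------------------------------------
    try:
        founders = simdata.simulate_founders(config.sim)
        off_geno, truth = simdata.simulate_polycross(founders, config.sim)
        design = simdata.assign_field_design(off_geno.sample_ids, config.sim)
        pheno, truth = simdata.simulate_phenotypes(
            truth, off_geno, design, config.traits, seed=config.seed)
        paths = simdata.write_simulation(out / "sim", founders, off_geno, truth,
                                         design, pheno)
    except Exception as e:  # noqa: BLE001 - stage boundary
        _fail("simulate", e)
    _finish_stage("simulate", paths)

    # -- QC and genomic matrices --------------------------------------------
    try:
        allg = GenotypeMatrix(
            np.concatenate([founders.genotypes.sample_ids, off_geno.sample_ids]),
            founders.genotypes.snp_ids.copy(),
            np.vstack([founders.genotypes.dosage, off_geno.dosage]),
        )
        filtered, report = filter_snps(allg, config.maf_min, config.max_snp_missing,
                                       config.max_ind_missing)
        complete = impute_missing(filtered, method=config.impute_method)
        G = compute_G_additive(complete)
        need_gd = any(MODEL_REGISTRY[m]["dominance"] and
                      MODEL_REGISTRY[m]["kernel"] == "G" for m in config.models)
        Gd = compute_G_dominance(complete) if need_gd else None
        qcdir = out / "relmat"
        qcdir.mkdir(exist_ok=True)
        G.to_tsv(qcdir / "G.tsv")
        (qcdir / "filter_report.json").write_text(
            json.dumps({k: v for k, v in asdict(report).items()
                        if not k.startswith("removed")}, sort_keys=True, indent=1))
        paths = [qcdir / "G.tsv", qcdir / "filter_report.json"]
        if Gd is not None:
            Gd.to_tsv(qcdir / "Gd.tsv")
            paths.append(qcdir / "Gd.tsv")
    except Exception as e:  # noqa: BLE001
        _fail("relmat", e)
    _finish_stage("relmat", paths)

    # -- pedigree reconstruction --------------------------------------------
    try:
        recon = pedrecon.reconstruct_pedigree(
            G, truth.recorded_pedigree, founders.female_ids, founders.male_ids,
            config.thresholds)
        pdir = out / "pedrecon"
        pdir.mkdir(exist_ok=True)
        recon.assignments.to_csv(pdir / "assignments.csv", index=False)
        recon.pedigree.to_csv(pdir / "pedigree_corrected.csv", index=False)
        contrib = recon.contribution
        (pdir / "contribution_test.json").write_text(json.dumps({
            "chi2": contrib.chi2, "df": contrib.df, "p_value": contrib.p_value,
            "expected_count": contrib.expected_count,
            "counts": contrib.counts_per_male.tolist(),
        } if contrib else {}, sort_keys=True, indent=1))
        paths = [pdir / "assignments.csv", pdir / "pedigree_corrected.csv",
                 pdir / "contribution_test.json"]
    except Exception as e:  # noqa: BLE001
        _fail("pedrecon", e)
    _finish_stage("pedrecon", paths)

    # -- kernels for the pedigree models -------------------------------------
    try:
        kernels = {"G": G}
        if Gd is not None:
            kernels["Gd"] = Gd
        need = {MODEL_REGISTRY[m]["kernel"] for m in config.models}
        if "A_PX" in need:
            kernels["A_PX"] = compute_A_additive(truth.recorded_pedigree)
        if "A_FS" in need:
            A_FS = compute_A_additive(recon.pedigree)
            kernels["A_FS"] = A_FS
            if any(MODEL_REGISTRY[m]["dominance"] and
                   MODEL_REGISTRY[m]["kernel"] == "A_FS" for m in config.models):
                kernels["Ad_FS"] = compute_A_dominance(recon.pedigree, A_FS)
        paths = []
    except Exception as e:  # noqa: BLE001
        _fail("kernels", e)
    _finish_stage("kernels", paths)

    # -- mixed-model fits -----------------------------------------------------
    try:
        mdir = out / "models"
        mdir.mkdir(exist_ok=True)
        fits: dict = {}
        rows = []
        paths = []
        multi_site = config.sim.n_sites > 1
        for trait in config.traits:
            for model in config.models:
                reg = MODEL_REGISTRY[model]
                terms = ["rep_in_site", "set_in_rep", "additive"]
                if multi_site:
                    terms.append("site_x_additive")
                kd = None
                if reg["dominance"]:
                    terms.append("dominance")
                    if multi_site:
                        terms.append("site_x_dominance")
                    kd = kernels["Gd" if reg["kernel"] == "G" else "Ad_FS"]
                spec = mlm.ModelSpec(
                    trait=trait.name, kernel_additive=kernels[reg["kernel"]],
                    kernel_dominance=kd, random_terms=tuple(terms),
                    covariates=tuple(trait.covariate_effects),
                    log_transform=trait.lognormal, label=model)
                fit = mlm.fit_model(pheno, spec)
                fits[(trait.name, model)] = fit
                h2, h2_se = mlm.heritability(fit)
                rb, rb_se = mlm.typeB_correlation(fit)
                rows.append({
                    "trait": trait.name, "model": model,
                    "sigma2_a": fit.vc.sigma2_a, "sigma2_sa": fit.vc.sigma2_sa,
                    "sigma2_d": fit.vc.sigma2_d, "sigma2_sd": fit.vc.sigma2_sd,
                    "mean_residual": fit.vc.mean_residual,
                    "h2": h2, "h2_se": h2_se, "rB": rb, "rB_se": rb_se,
                    "loglik": fit.loglik_reml, "aic": fit.aic,
                    "converged": fit.converged,
                })
                bv = fit.blups["additive"]
                p = mdir / f"blup_{trait.name}_{model}.csv"
                bv.to_csv(p, index=False, float_format="%.10g")
                paths.append(p)
        comp = pd.DataFrame(rows)
        comp_path = mdir / "model_comparison.csv"
        comp.to_csv(comp_path, index=False, float_format="%.10g")
        paths.append(comp_path)
    except Exception as e:  # noqa: BLE001
        _fail("models", e)
    _finish_stage("models", paths)

    # -- selection ------------------------------------------------------------
    try:
        sdir = out / "selection"
        sdir.mkdir(exist_ok=True)
        offspring = [i for i in off_geno.sample_ids]
        rel_ns = compute_A_additive(recon.pedigree)
        rows = []
        for trait in config.traits:
            ref_fit = fits[(trait.name, config.reference_model)]
            ref_bv = (ref_fit.blups["additive"].set_index("id")["blup"]
                      .loc[offspring])
            yvals = pheno[trait.name].to_numpy(float)
            pop_mean = float(np.mean(np.log(yvals) if trait.lognormal else yvals))
            for model in config.models:
                bv = (fits[(trait.name, model)].blups["additive"]
                      .set_index("id")["blup"].loc[offspring])
                rep = selection.corrected_gain(
                    bv, ref_bv, pop_mean, fraction=config.selection_fraction,
                    model_label=model, rel_for_ns=rel_ns)
                rows.append({
                    "trait": trait.name, "model": model,
                    "n_selected": len(rep.selected_ids),
                    "mean_bv": rep.mean_bv, "gain_percent": rep.gain_percent,
                    "status_number": rep.status_number,
                    "corrected_mean_bv": rep.corrected_mean_bv,
                    "corrected_gain_percent": rep.corrected_gain_percent,
                    "overlap_percent_vs_reference": rep.overlap_percent_vs_reference,
                    "overestimation_percent": rep.overestimation_percent,
                })
        sel_path = sdir / "selection_report.csv"
        pd.DataFrame(rows).to_csv(sel_path, index=False, float_format="%.10g")
        paths = [sel_path]
    except Exception as e:  # noqa: BLE001
        _fail("selection", e)
    _finish_stage("selection", paths)

    manifest["files"] = {str(p.relative_to(out)): _sha256(p) for p in outputs}
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
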