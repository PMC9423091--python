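"""Individual-tree mixed models by average-information REML.

Implements the five model variants used to analyze multi-site progeny
trials:

* additive models (pedigree or genomic kernel)::

      y = Xb + Z1 rep(site) + Z2 set(rep) + Z3 a + Z4 sa + e

* additive + dominance models add ``+ Z5 d + Z6 sd``.

``a`` (breeding values) and ``d`` (dominance deviations) follow
``N(0, s2 K)`` for an additive or dominance relationship kernel ``K``;
``sa``/``sd`` are independent per-site realizations with within-site
covariance proportional to the same kernel (a block-diagonal
main-plus-interaction parameterization); residuals are heterogeneous by
site.  Estimation is average-information (AI) REML with EM fallback
steps, variance components floored at a small positive multiple of the
phenotypic variance, and BLUPs/standard errors from the converged mixed
model.

Derived quantities: narrow/broad-sense heritability, the type-B genetic
correlation ``rB = s2_a / (s2_a + s2_sa)`` measuring G x E, likelihood-
ratio tests for single components, per-individual theoretical accuracy
``sqrt(1 - SE^2 / ((1 + F) s2_a))``, adjusted phenotypes, and bivariate
genetic correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .relmat import IntegrityError, RelationshipMatrix

GENETIC_TERMS = ("additive", "site_x_additive", "dominance", "site_x_dominance")
FACTOR_TERMS = ("rep_in_site", "set_in_rep")


class UsageError(ValueError):
    pass


class NumericError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Declarative description of one univariate fit."""

    trait: str
    kernel_additive: RelationshipMatrix | None = None
    kernel_dominance: RelationshipMatrix | None = None
    random_terms: tuple = ("rep_in_site", "set_in_rep", "additive", "site_x_additive")
    covariates: tuple = ()
    log_transform: bool = False
    constrained_components: dict = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.random_terms) - set(GENETIC_TERMS) - set(FACTOR_TERMS)
        if unknown:
            raise UsageError(f"unknown random term(s): {sorted(unknown)}")
        if "additive" not in self.random_terms:
            raise UsageError("the additive term is present in every model")
        if "site_x_dominance" in self.random_terms and "dominance" not in self.random_terms:
            raise UsageError("site_x_dominance requires dominance")
        if self.kernel_additive is None:
            raise UsageError("an additive kernel is required")
        if ("dominance" in self.random_terms) and self.kernel_dominance is None:
            raise UsageError("dominance terms require a dominance kernel")


@dataclass
class VarianceComponents:
    sigma2_a: float = 0.0
    sigma2_sa: float = 0.0
    sigma2_d: float = 0.0
    sigma2_sd: float = 0.0
    sigma2_rep: float = 0.0
    sigma2_set: float = 0.0
    sigma2_e_by_site: dict = field(default_factory=dict)
    cov: pd.DataFrame | None = None  # asymptotic covariance of estimates
    boundary: tuple = ()

    @property
    def mean_residual(self) -> float:
        """Unweighted mean of the per-site residual variances."""
        if not self.sigma2_e_by_site:
            raise ValueError("no residual variances recorded")
        return float(np.mean(list(self.sigma2_e_by_site.values())))


@dataclass
class ModelFit:
    spec: ModelSpec
    vc: VarianceComponents
    loglik_reml: float
    aic: float
    fixed_estimates: pd.Series
    blups: dict
    converged: bool
    n_iter: int
    n_obs: int
    theta: dict
    _ids: np.ndarray | None = None


@dataclass
class LRTResult:
    stat: float
    df: int
    p_value: float
    p_value_mixture: float


# ---------------------------------------------------------------------------
# REML core
# ---------------------------------------------------------------------------


@dataclass
class _Component:
    name: str
    C: np.ndarray          # n x n covariance structure per unit parameter
    em_dim: int            # latent dimension for the EM fallback update
    nonneg: bool = True    # False for covariance (cross) parameters


def _loglik_only(y, X, V):
    n, p = X.shape
    jitter = 0.0
    for _ in range(4):
        try:
            L = linalg.cholesky(V + jitter * np.eye(n), lower=True)
            break
        except linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-8 * np.trace(V) / n)
    else:
        raise NumericError("covariance matrix not positive definite after jitter")
    Viy = linalg.cho_solve((L, True), y)
    ViX = linalg.cho_solve((L, True), X)
    XtViX = X.T @ ViX
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise NumericError("X'V^-1X not positive definite (rank-deficient fixed effects?)")
    beta = np.linalg.solve(XtViX, ViX.T @ y)
    Py = Viy - ViX @ beta
    logdet_v = 2.0 * np.sum(np.log(np.diag(L)))
    ll = -0.5 * (logdet_v + logdet_x + float(y @ Py) + (n - p) * np.log(2.0 * np.pi))
    return ll, L, Py, beta, XtViX


def _reml(
    y: np.ndarray,
    X: np.ndarray,
    components: list,
    init: dict | None = None,
    constrained: dict | None = None,
    clamp=None,
    tol_ll: float = 1e-8,
    tol_par: float = 1e-6,
    max_iter: int = 200,
    n_em: int = 3,
):
    """Average-information REML with EM fallback.

    ``components`` define ``V = sum_k theta_k C_k``.  ``constrained``
    holds named parameters fixed.  ``clamp`` is an optional callable
    applied to the parameter dict after each proposal (used to keep
    covariance blocks positive semi-definite).  Returns a result dict.
    """
    n, p = X.shape
    constrained = dict(constrained or {})
    names = [c.name for c in components]
    resid_ols = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    vtot = float(resid_ols @ resid_ols) / max(n - p, 1)
    floor = 1e-8 * vtot

    theta = {}
    free = [nm for nm in names if nm not in constrained]
    n_var_free = sum(1 for c in components if c.nonneg and c.name in free)
    for c in components:
        if c.name in constrained:
            theta[c.name] = float(constrained[c.name])
        elif not c.nonneg:
            theta[c.name] = 0.0
        else:
            theta[c.name] = vtot / max(n_var_free, 1)
    if init:
        for k, v in init.items():
            if k in free:
                theta[k] = float(v)

    def _apply_bounds(th):
        out = dict(th)
        for c in components:
            if c.name in constrained:
                out[c.name] = float(constrained[c.name])
            elif c.nonneg:
                out[c.name] = max(out[c.name], floor)
        if clamp is not None:
            out = clamp(out)
            for k, v in constrained.items():
                out[k] = float(v)
        return out

    def _V(th):
        V = np.zeros((n, n))
        for c in components:
            V += th[c.name] * c.C
        return V

    theta = _apply_bounds(theta)
    ll, L, Py, beta, XtViX = _loglik_only(y, X, _V(theta))
    ll_trace = [ll]
    converged = False
    ai_free = None
    pinned: set = set()        # components fixed at the floor
    pin_count: dict = {}
    it = 0
    for it in range(1, max_iter + 1):
        active = [nm for nm in free if nm not in pinned]
        # full evaluation: P explicit for traces
        Vi = linalg.cho_solve((L, True), np.eye(n))
        ViX = Vi @ X
        P = Vi - ViX @ np.linalg.solve(X.T @ ViX, ViX.T)
        u = {c.name: c.C @ Py for c in components}
        grad = {}
        for c in components:
            tr = float(np.sum(P * c.C))
            grad[c.name] = -0.5 * (tr - float(Py @ u[c.name]))
        w = {nm: P @ u[nm] for nm in free}
        ai = np.array([[0.5 * float(u[a] @ w[b]) for b in free] for a in free])
        ai_act = np.array([[0.5 * float(u[a] @ w[b]) for b in active] for a in active])

        proposal = None
        if it > n_em and len(active):
            g = np.array([grad[nm] for nm in active])
            ridge = 1e-8 * max(np.trace(ai_act) / max(len(active), 1), 1.0)
            try:
                delta = np.linalg.solve(ai_act + ridge * np.eye(len(active)), g)
                proposal = ("ai", delta)
            except np.linalg.LinAlgError:
                proposal = None

        accepted = None
        if proposal is not None:
            _, delta = proposal
            step = 1.0
            for _ in range(8):
                cand = dict(theta)
                for j, nm in enumerate(active):
                    cand[nm] = theta[nm] + step * delta[j]
                cand = _apply_bounds(cand)
                try:
                    ll_c, L_c, Py_c, beta_c, XtViX_c = _loglik_only(y, X, _V(cand))
                except NumericError:
                    step *= 0.5
                    continue
                if ll_c >= ll - 1e-10:
                    accepted = (cand, ll_c, L_c, Py_c, beta_c, XtViX_c)
                    break
                step *= 0.5
        if accepted is None:
            # EM fallback: monotone update of the variance parameters
            cand = dict(theta)
            for c in components:
                if c.name in active and c.nonneg:
                    cand[c.name] = theta[c.name] + 2.0 * theta[c.name] ** 2 \
                        * grad[c.name] / max(c.em_dim, 1)
            cand = _apply_bounds(cand)
            ll_c, L_c, Py_c, beta_c, XtViX_c = _loglik_only(y, X, _V(cand))
            accepted = (cand, ll_c, L_c, Py_c, beta_c, XtViX_c)

        cand, ll_c, L, Py, beta, XtViX = accepted
        d_par = max((abs(cand[nm] - theta[nm]) / (abs(theta[nm]) + vtot * 1e-12 + 1.0)
                     for nm in active), default=0.0)
        d_ll = abs(ll_c - ll)
        theta, ll = cand, ll_c
        ll_trace.append(ll)
        ai_free = ai
        # a variance component that keeps hugging the floor with a negative
        # gradient is pinned there, so the AI system stays well conditioned
        for c in components:
            nm = c.name
            if nm in active and c.nonneg:
                at_floor = theta[nm] <= floor * (1.0 + 1e-6) and grad[nm] < 0
                pin_count[nm] = pin_count.get(nm, 0) + 1 if at_floor else 0
                if pin_count[nm] >= 2:
                    pinned.add(nm)
                    theta[nm] = floor
        if d_ll < tol_ll * (1.0 + abs(ll)) and d_par < tol_par:
            converged = True
            break

    if not converged:
        warnings.warn(f"REML did not converge in {max_iter} iterations")

    # asymptotic covariance of the free parameter estimates from the AI matrix
    cov = None
    if ai_free is not None and len(free):
        try:
            cov_free = np.linalg.inv(ai_free + 1e-12 * np.eye(len(free)))
        except np.linalg.LinAlgError:
            cov_free = np.linalg.pinv(ai_free)
        cov = pd.DataFrame(0.0, index=names, columns=names)
        for a, na in enumerate(free):
            for b, nb in enumerate(free):
                cov.loc[na, nb] = cov_free[a, b]

    Vi = linalg.cho_solve((L, True), np.eye(n))
    ViX = Vi @ X
    P = Vi - ViX @ np.linalg.solve(X.T @ ViX, ViX.T)
    boundary = tuple(nm for nm in free
                     if any(c.name == nm and c.nonneg for c in components)
                     and theta[nm] <= floor * (1.0 + 1e-6))
    return {
        "theta": theta, "loglik": ll, "beta": beta, "P": P, "Py": Py,
        "cov": cov, "converged": converged, "n_iter": it,
        "boundary": boundary, "free": free, "floor": floor,
        "ll_trace": ll_trace,
    }


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------


def _one_hot(labels) -> tuple[np.ndarray, list]:
    levels = sorted(set(labels))
    Z = np.zeros((len(labels), len(levels)))
    idx = {l: j for j, l in enumerate(levels)}
    for i, l in enumerate(labels):
        Z[i, idx[l]] = 1.0
    return Z, levels


def _design_frames(pheno: pd.DataFrame, spec: ModelSpec):
    required = {"id", "site"} | set(spec.covariates) | {spec.trait}
    if "rep_in_site" in spec.random_terms:
        required.add("rep")
    if "set_in_rep" in spec.random_terms:
        required |= {"rep", "set"}
    missing = required - set(pheno.columns)
    if missing:
        raise IntegrityError(f"phenotype table lacks column(s) {sorted(missing)}")
    data = pheno.dropna(subset=[spec.trait]).reset_index(drop=True)
    y = data[spec.trait].to_numpy(float)
    if spec.log_transform:
        if (y <= 0).any():
            raise IntegrityError("log transform requires strictly positive phenotypes")
        y = np.log(y)
    Xs, _ = _one_hot(data["site"])
    X = np.column_stack([Xs] + [data[c].to_numpy(float) for c in spec.covariates])
    fixed_names = [f"site:{s}" for s in sorted(set(data["site"]))] + list(spec.covariates)
    return data, y, X, fixed_names


def _build_components(data: pd.DataFrame, spec: ModelSpec):
    n = len(data)
    ids = data["id"].to_numpy(object)
    sites = data["site"].to_numpy(object)
    same_site = (sites[:, None] == sites[None, :]).astype(float)
    comps, meta = [], {}
    for term in spec.random_terms:
        if term == "rep_in_site":
            Z, levels = _one_hot(data["site"].astype(str) + ":" + data["rep"].astype(str))
            comps.append(_Component(term, Z @ Z.T, em_dim=len(levels)))
            meta[term] = {"Z": Z, "levels": levels}
        elif term == "set_in_rep":
            Z, levels = _one_hot(data["site"].astype(str) + ":" + data["rep"].astype(str)
                                 + ":" + data["set"].astype(str))
            comps.append(_Component(term, Z @ Z.T, em_dim=len(levels)))
            meta[term] = {"Z": Z, "levels": levels}
        elif term in ("additive", "site_x_additive"):
            K = spec.kernel_additive
            idx = K.index(ids)
            B = K.values[np.ix_(idx, idx)]
            C = B if term == "additive" else B * same_site
            comps.append(_Component(term, C, em_dim=n))
            meta[term] = {"kernel": K, "idx": idx}
        elif term in ("dominance", "site_x_dominance"):
            K = spec.kernel_dominance
            idx = K.index(ids)
            B = K.values[np.ix_(idx, idx)]
            C = B if term == "dominance" else B * same_site
            comps.append(_Component(term, C, em_dim=n))
            meta[term] = {"kernel": K, "idx": idx}
    site_levels = sorted(set(sites))
    for s in site_levels:
        comps.append(_Component(f"resid:{s}", np.diag((sites == s).astype(float)),
                                em_dim=int((sites == s).sum())))
    return comps, meta, site_levels


def fit_model(pheno: pd.DataFrame, spec: ModelSpec, compute_blups: bool = True,
              max_iter: int = 200) -> ModelFit:
    """Fit one individual-tree model by AI-REML.

    ``pheno`` holds one row per tree with columns ``id``, ``site`` (and
    ``rep``/``set`` when those terms are modeled), any fixed covariates,
    and the trait.  Rows with a missing trait value are dropped.  Variance
    components named in ``spec.constrained_components`` are held fixed
    during maximization.
    """
    data, y, X, fixed_names = _design_frames(pheno, spec)
    comps, meta, site_levels = _build_components(data, spec)
    res = _reml(y, X, comps, constrained=spec.constrained_components,
                max_iter=max_iter)
    theta = res["theta"]

    vc = VarianceComponents(
        sigma2_a=theta.get("additive", 0.0),
        sigma2_sa=theta.get("site_x_additive", 0.0),
        sigma2_d=theta.get("dominance", 0.0),
        sigma2_sd=theta.get("site_x_dominance", 0.0),
        sigma2_rep=theta.get("rep_in_site", 0.0),
        sigma2_set=theta.get("set_in_rep", 0.0),
        sigma2_e_by_site={s: theta[f"resid:{s}"] for s in site_levels},
        cov=res["cov"],
        boundary=res["boundary"],
    )
    k_free = sum(1 for nm in res["free"] if nm not in res["boundary"])
    aic = -2.0 * res["loglik"] + 2.0 * k_free

    blups: dict = {}
    if compute_blups:
        P, Py = res["P"], res["Py"]
        for term in spec.random_terms:
            th = theta[term]
            if term in FACTOR_TERMS:
                Z = meta[term]["Z"]
                ZtPy = Z.T @ Py
                u = th * ZtPy
                pev = th - th**2 * np.einsum("ij,jk,ki->i", Z.T, P, Z)
                blups[term] = pd.DataFrame({
                    "level": meta[term]["levels"], "blup": u,
                    "se": np.sqrt(np.clip(pev, 0.0, None)),
                })
            elif term in ("additive", "dominance"):
                K = meta[term]["kernel"]
                idx = meta[term]["idx"]
                KZt = K.values[:, idx]                   # m x n
                u = th * (KZt @ Py)
                KZtP = KZt @ P
                pev = th * np.diag(K.values) - th**2 * np.einsum(
                    "ij,ij->i", KZtP, KZt)
                blups[term] = pd.DataFrame({
                    "id": K.ids, "blup": u,
                    "se": np.sqrt(np.clip(pev, 0.0, None)),
                })
            # site-interaction BLUPs are rarely consumed individually; skip

    return ModelFit(
        spec=spec, vc=vc, loglik_reml=res["loglik"], aic=aic,
        fixed_estimates=pd.Series(res["beta"], index=fixed_names),
        blups=blups, converged=res["converged"], n_iter=res["n_iter"],
        n_obs=len(y), theta=theta, _ids=data["id"].to_numpy(object),
    )


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


def _vc_of(fit_or_vc) -> VarianceComponents:
    return fit_or_vc.vc if isinstance(fit_or_vc, ModelFit) else fit_or_vc


def _delta_se(vc: VarianceComponents, grad: dict) -> float | None:
    if vc.cov is None:
        return None
    names = [nm for nm in grad if nm in vc.cov.index]
    if not names:
        return None
    g = np.array([grad[nm] for nm in names])
    V = vc.cov.loc[names, names].to_numpy()
    var = float(g @ V @ g)
    return float(np.sqrt(max(var, 0.0)))


def heritability(fit_or_vc, mode: str = "narrow") -> tuple[float, float | None]:
    """Individual-tree heritability with a delta-method standard error.

    narrow:  h2 = s2_a / s2_P
    broad:   H2 = (s2_a + s2_d) / s2_P

    with the phenotypic variance ``s2_P = s2_a + s2_sa + s2_d + s2_sd +
    mean_e`` summing every genetic component in the model plus the
    unweighted mean of the per-site residual variances.  The SE is None
    when no estimate covariance is available.
    """
    vc = _vc_of(fit_or_vc)
    ebar = vc.mean_residual
    n_sites = len(vc.sigma2_e_by_site)
    den = vc.sigma2_a + vc.sigma2_sa + vc.sigma2_d + vc.sigma2_sd + ebar
    if mode == "narrow":
        num = vc.sigma2_a
    elif mode == "broad":
        num = vc.sigma2_a + vc.sigma2_d
    else:
        raise UsageError(f"unknown heritability mode {mode!r}")
    if den <= 0:
        raise ZeroDivisionError("zero phenotypic variance; heritability undefined")
    h2 = num / den
    grad = {}
    for nm, in_num in (("additive", True), ("site_x_additive", False),
                       ("dominance", mode == "broad"),
                       ("site_x_dominance", False)):
        grad[nm] = ((den - num) / den**2) if in_num else (-num / den**2)
    # note: for A-only models the dominance entries are absent from the
    # estimate covariance and drop out of the delta sum
    for s in vc.sigma2_e_by_site:
        grad[f"resid:{s}"] = (-num / den**2) / n_sites
    return float(h2), _delta_se(vc, grad)


def typeB_correlation(fit_or_vc) -> tuple[float | None, float | None]:
    """Type-B additive genetic correlation across sites.

    ``rB = s2_a / (s2_a + s2_sa)``; equals 1 by definition when the model
    has no site-by-additive term.  Returns (rB, SE) with a delta-method
    SE, or (None, None) when both components are zero.
    """
    vc = _vc_of(fit_or_vc)
    a, sa = vc.sigma2_a, vc.sigma2_sa
    if a + sa <= 0:
        return None, None
    rb = a / (a + sa)
    grad = {"additive": sa / (a + sa) ** 2, "site_x_additive": -a / (a + sa) ** 2}
    return float(rb), _delta_se(vc, grad)


def lrt_component(full: ModelFit, reduced: ModelFit) -> LRTResult:
    """Likelihood-ratio test for the single random term dropped in
    ``reduced``; the plain chi-square(1) p-value is primary, with the
    boundary-corrected mixture (0.5 chi2_0 + 0.5 chi2_1) alongside."""
    tf, tr = set(full.spec.random_terms), set(reduced.spec.random_terms)
    if not (tr <= tf and len(tf - tr) <= 1):
        raise UsageError("reduced model must drop exactly one random term of the full model")
    if list(full.fixed_estimates.index) != list(reduced.fixed_estimates.index):
        raise UsageError("models must share the same fixed effects")
    stat = max(0.0, 2.0 * (full.loglik_reml - reduced.loglik_reml))
    p = float(stats.chi2.sf(stat, df=1))
    p_mix = 1.0 if stat == 0.0 else 0.5 * p
    return LRTResult(stat=stat, df=1, p_value=p, p_value_mixture=p_mix)


def theoretical_accuracy(fit: ModelFit, sigma2_a: float | None = None) -> pd.DataFrame:
    """Per-individual theoretical accuracy of estimated breeding values.

    ``accuracy = sqrt(1 - SE^2 / ((1 + F) s2_a))`` clipped to [0, 1],
    with ``1 + F`` the diagonal of the additive kernel.  ``sigma2_a``
    may be supplied externally for cross-model comparisons of fits with
    constrained components.
    """
    if "additive" not in fit.blups:
        raise IntegrityError("fit carries no additive BLUPs (compute_blups=False?)")
    s2a = fit.vc.sigma2_a if sigma2_a is None else float(sigma2_a)
    if s2a <= 0:
        raise UsageError("theoretical accuracy requires a positive additive variance")
    tab = fit.blups["additive"]
    K = fit.spec.kernel_additive
    diag = pd.Series(np.diag(K.values), index=K.ids)
    one_plus_f = diag.loc[tab["id"]].to_numpy()
    if tab["se"].isna().any():
        raise IntegrityError("missing BLUP standard errors")
    rel = 1.0 - tab["se"].to_numpy() ** 2 / (one_plus_f * s2a)
    return pd.DataFrame({
        "id": tab["id"],
        "breeding_value": tab["blup"],
        "se": tab["se"],
        "inbreeding_F": one_plus_f - 1.0,
        "accuracy": np.sqrt(np.clip(rel, 0.0, 1.0)),
    })


def adjusted_phenotypes(pheno: pd.DataFrame, spec: ModelSpec) -> pd.Series:
    """Residuals from the non-genetic part of the model.

    Fits the model with the genetic terms removed and returns
    ``y* = y - Xb - rep/set BLUPs`` indexed by tree id, on the modeling
    (possibly log) scale.
    """
    nongen = tuple(t for t in spec.random_terms if t in FACTOR_TERMS)
    data, y, X, _ = _design_frames(pheno, spec)
    if not nongen:
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        return pd.Series(y - X @ beta, index=data["id"], name=spec.trait)
    meta = {}
    keep = []
    for term in nongen:
        if term == "rep_in_site":
            Z, levels = _one_hot(data["site"].astype(str) + ":" + data["rep"].astype(str))
        else:
            Z, levels = _one_hot(data["site"].astype(str) + ":" + data["rep"].astype(str)
                                 + ":" + data["set"].astype(str))
        keep.append(_Component(term, Z @ Z.T, em_dim=len(levels)))
        meta[term] = {"Z": Z, "levels": levels}
    sites = data["site"].to_numpy(object)
    for s in sorted(set(sites)):
        keep.append(_Component(f"resid:{s}", np.diag((sites == s).astype(float)),
                               em_dim=int((sites == s).sum())))
    res = _reml(y, X, keep)
    fitted = X @ res["beta"]
    for term in nongen:
        Z = meta[term]["Z"]
        fitted += res["theta"][term] * (Z @ (Z.T @ res["Py"]))
    return pd.Series(y - fitted, index=data["id"], name=spec.trait)


# ---------------------------------------------------------------------------
# bivariate genetic correlation
# ---------------------------------------------------------------------------


def genetic_correlation_bivariate(
    pheno: pd.DataFrame,
    trait1: str,
    trait2: str,
    kernel: RelationshipMatrix,
    log_transform: tuple = (False, False),
    max_iter: int = 200,
) -> dict:
    """Additive genetic correlation between two traits by bivariate REML.

    The model stacks both traits with per-trait site means as fixed
    effects, an unstructured 2x2 additive covariance sharing the kernel,
    and an unstructured 2x2 residual covariance per site.  Returns a dict
    with ``r_g`` (constrained to [-1, 1]), ``se``, ``significant``
    (|r_g| >= 2 SE), and the additive (co)variances.  On non-convergence
    it falls back to the correlation of univariate BLUPs with a warning.
    """
    data = pheno.dropna(subset=[trait1, trait2]).reset_index(drop=True)
    if data.empty:
        raise IntegrityError("no individuals share both traits")
    ids = data["id"].to_numpy(object)
    n = len(ids)
    y1 = data[trait1].to_numpy(float)
    y2 = data[trait2].to_numpy(float)
    if log_transform[0]:
        y1 = np.log(y1)
    if log_transform[1]:
        y2 = np.log(y2)
    y = np.concatenate([y1, y2])
    Xs, _ = _one_hot(data["site"])
    X = linalg.block_diag(Xs, Xs)

    idx = kernel.index(ids)
    B = kernel.values[np.ix_(idx, idx)]
    Z = np.zeros((n, n))
    comps = []
    blocks = {
        "a11": np.block([[B, Z], [Z, Z]]),
        "a12": np.block([[Z, B], [B, Z]]),
        "a22": np.block([[Z, Z], [Z, B]]),
    }
    for nm, C in blocks.items():
        comps.append(_Component(nm, C, em_dim=n, nonneg=(nm != "a12")))
    sites = data["site"].to_numpy(object)
    site_levels = sorted(set(sites))
    for s in site_levels:
        D = np.diag((sites == s).astype(float))
        ns = int((sites == s).sum())
        comps.append(_Component(f"e11:{s}", np.block([[D, Z], [Z, Z]]), em_dim=ns))
        comps.append(_Component(f"e12:{s}", np.block([[Z, D], [D, Z]]), em_dim=ns,
                                nonneg=False))
        comps.append(_Component(f"e22:{s}", np.block([[Z, Z], [Z, D]]), em_dim=ns))

    def _psd_clamp(th):
        out = dict(th)
        cap = 0.999
        c = out["a12"]
        lim = cap * np.sqrt(out["a11"] * out["a22"])
        out["a12"] = float(np.clip(c, -lim, lim))
        for s in site_levels:
            lim = cap * np.sqrt(out[f"e11:{s}"] * out[f"e22:{s}"])
            out[f"e12:{s}"] = float(np.clip(out[f"e12:{s}"], -lim, lim))
        return out

    # initialize cross terms from the phenotypic covariance sign
    init = {"a12": 0.5 * float(np.cov(y1, y2)[0, 1])}
    res = _reml(y, X, comps, init=init, clamp=_psd_clamp, max_iter=max_iter)
    th = res["theta"]
    if not res["converged"]:
        warnings.warn("bivariate REML did not converge; falling back to the "
                      "correlation of univariate BLUPs")
        fits = []
        for tr, lg in ((trait1, log_transform[0]), (trait2, log_transform[1])):
            spec = ModelSpec(trait=tr, kernel_additive=kernel,
                             random_terms=("additive",), log_transform=lg)
            fits.append(fit_model(data, spec))
        b1 = fits[0].blups["additive"].set_index("id")["blup"]
        b2 = fits[1].blups["additive"].set_index("id")["blup"]
        r = float(np.corrcoef(b1.loc[ids], b2.loc[ids])[0, 1])
        return {"r_g": r, "se": None, "significant": None, "converged": False,
                "sigma2_a": (fits[0].vc.sigma2_a, fits[1].vc.sigma2_a),
                "cov_a": None, "method": "blup_correlation"}

    a11, a12, a22 = th["a11"], th["a12"], th["a22"]
    r = float(np.clip(a12 / np.sqrt(a11 * a22), -1.0, 1.0))
    if abs(r) >= 0.999:  # the interior PSD clamp: report the boundary value
        r = float(np.copysign(1.0, r))
    se = None
    if res["cov"] is not None:
        g = {
            "a11": -a12 / (2.0 * a11**1.5 * np.sqrt(a22)),
            "a12": 1.0 / np.sqrt(a11 * a22),
            "a22": -a12 / (2.0 * a22**1.5 * np.sqrt(a11)),
        }
        names = list(g)
        gv = np.array([g[nm] for nm in names])
        V = res["cov"].loc[names, names].to_numpy()
        se = float(np.sqrt(max(gv @ V @ gv, 0.0)))
    return {"r_g": r, "se": se,
            "significant": (None if se is None else bool(abs(r) >= 2.0 * se)),
            "converged": True, "sigma2_a": (a11, a22), "cov_a": a12,
            "method": "bivariate_reml"}
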