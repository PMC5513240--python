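"""Trait x environment analysis: allometry, spatial screening, Poisson GLMM.

The question is whether a functional trait modulates how species
abundance responds to the microhabitat: the model is

    y_ij ~ Poisson(exp(a0 + a1 X_i + b1 Z_j + b2 X_i Z_j + eps_j + gam_i))

with X_i the environment at site i, Z_j the trait of species j, b2 the
environment-trait interaction, and crossed random intercepts for species
(eps_j) and sites (gam_i).  Fitting is by Laplace-approximate maximum
likelihood; models are compared by AIC/Akaike weights and likelihood
ratio tests, and the trait's contribution to the between-species variance
is the proportional variance reduction c_beta.

Before modelling, quantitative morphometrics are size-adjusted on the
log10 scale (common allometric slope), and spatial non-independence of
sites is screened with Moran's I and Geary's C randomization tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._errors import ContractError, DegenerateDataError, DomainError
from .io import Dataset, counts_matrix

__all__ = [
    "SpatialWeights", "GlmmSpec", "ModelFit",
    "allometric_adjust", "inverse_distance_weights",
    "spatial_autocorrelation_test", "build_trait_env_design",
    "fit_trait_env_glmm", "compare_models", "c_beta",
]


# ---------------------------------------------------------------------------
# allometric size correction

def allometric_adjust(records: pd.DataFrame,
                      slope_mode: str = "pooled_within_group"):
    """Remove body-size allometry from a trait measurement.

    ``records`` needs columns ``y`` (trait, mm), ``x`` (standard length,
    mm) and ``group`` (species).  The adjusted value is

        M_adj = log10 y - beta * (log10 x - mean(log10 x))

    with the mean taken over all individuals and beta the least-squares
    slope of log10 y on log10 x: fitted within groups around group means
    and pooled (``pooled_within_group``, the default, robust when groups
    differ in size range) or separately per group (``per_group``).

    Returns (adjusted values as a Series, beta) where beta is a float for
    the pooled mode and a dict group -> slope otherwise.
    """
    if not {"y", "x", "group"} <= set(records.columns):
        raise DomainError("records must have columns y, x, group")
    if (records["y"] <= 0).any() or (records["x"] <= 0).any():
        raise DomainError("measurements must be strictly positive")
    ly = np.log10(records["y"].to_numpy(float))
    lx = np.log10(records["x"].to_numpy(float))
    grand_mean = lx.mean()
    groups = records["group"].to_numpy()

    def _slope(lx_g, ly_g):
        dx = lx_g - lx_g.mean()
        ss = (dx**2).sum()
        if ss == 0:
            raise DegenerateDataError("zero variance in log x: slope undefined")
        return ((dx * (ly_g - ly_g.mean())).sum(), ss)

    if slope_mode == "pooled_within_group":
        num = den = 0.0
        for g in np.unique(groups):
            m = groups == g
            if m.sum() < 3:
                raise DomainError(f"group {g!r} has fewer than 3 records")
            n_, d_ = _slope(lx[m], ly[m])
            num, den = num + n_, den + d_
        if den == 0:
            raise DegenerateDataError("zero variance in log x: slope undefined")
        beta = num / den
        adj = ly - beta * (lx - grand_mean)
        return pd.Series(adj, index=records.index), float(beta)
    if slope_mode == "per_group":
        betas = {}
        adj = np.empty_like(ly)
        for g in np.unique(groups):
            m = groups == g
            if m.sum() < 3:
                raise DomainError(f"group {g!r} has fewer than 3 records")
            n_, d_ = _slope(lx[m], ly[m])
            betas[g] = n_ / d_
            adj[m] = ly[m] - betas[g] * (lx[m] - grand_mean)
        return pd.Series(adj, index=records.index), betas
    raise DomainError(f"unknown slope_mode {slope_mode!r}")


# ---------------------------------------------------------------------------
# spatial autocorrelation

@dataclass
class SpatialWeights:
    """Symmetric non-negative site weights with zero diagonal."""

    w: np.ndarray
    site_ids: list[str] | None = None

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 2 or self.w.shape[0] != self.w.shape[1]:
            raise DomainError("weights must be a square matrix")
        if np.any(np.diag(self.w) != 0):
            raise DomainError("weight diagonal must be zero")
        if np.any(self.w < 0):
            raise DomainError("weights must be non-negative")
        if not np.allclose(self.w, self.w.T):
            raise DomainError("weights must be symmetric")
        if self.w.sum() == 0:
            raise DomainError("at least one weight must be positive")


def inverse_distance_weights(positions: np.ndarray,
                             site_ids=None) -> SpatialWeights:
    """Inverse along-stream-distance weights (row-unstandardized), the
    natural scheme for sites strung along a single reach."""
    pos = np.asarray(positions, dtype=float)
    if pos.ndim == 1:
        pos = pos[:, None]
    d = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1))
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    if np.isinf(w).any():
        raise DomainError("duplicate positions give infinite weights")
    return SpatialWeights(w, list(site_ids) if site_ids is not None else None)


def spatial_autocorrelation_test(values: np.ndarray, w: SpatialWeights,
                                 statistic: str = "moran",
                                 n_perm: int = 999,
                                 seed: int | None = None):
    """Moran's I or Geary's C with a two-sided permutation p-value.

    Moran's I = (n/S0) * sum_ij w_ij z_i z_j / sum z_i^2  (z centered);
    Geary's C = ((n-1)/(2 S0)) * sum_ij w_ij (x_i - x_j)^2 / sum z_i^2.
    The null permutes the values over sites; the p-value compares the
    observed deviation from the permutation mean with the null deviations
    (add-one estimator).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise DomainError("need at least 4 sites")
    if np.ptp(x) == 0:
        raise DegenerateDataError("values are constant")
    if w.w.shape[0] != n:
        raise DomainError("weights and values differ in length")
    W = w.w
    s0 = W.sum()

    def _stat(v):
        z = v - v.mean()
        denom = (z**2).sum()
        if statistic == "moran":
            return (n / s0) * (z @ W @ z) / denom
        if statistic == "geary":
            diff2 = (v[:, None] - v[None, :]) ** 2
            return ((n - 1) / (2 * s0)) * (W * diff2).sum() / denom
        raise DomainError(f"unknown statistic {statistic!r}")

    observed = float(_stat(x))
    rng = np.random.default_rng(seed)
    null = np.array([_stat(rng.permutation(x)) for _ in range(n_perm)])
    centre = null.mean()
    p = (1.0 + np.sum(np.abs(null - centre) >= abs(observed - centre))) \
        / (n_perm + 1.0)
    return observed, float(p)


# ---------------------------------------------------------------------------
# design construction

@dataclass
class GlmmSpec:
    """Fixed- and random-effect layout of one trait x environment model."""

    env_name: str
    trait_name: str
    env_cols: list[str]
    trait_col: str
    interaction_cols: list[str]
    include_interaction: bool = True
    include_trait: bool = True
    response: str = "count"
    site_col: str = "site_id"
    species_col: str = "species"

    def fixed_columns(self) -> list[str]:
        cols = list(self.env_cols)
        if self.include_trait:
            cols.append(self.trait_col)
        if self.include_interaction:
            cols += list(self.interaction_cols)
        return cols

    def without_interaction(self) -> "GlmmSpec":
        return GlmmSpec(self.env_name, self.trait_name, self.env_cols,
                        self.trait_col, self.interaction_cols,
                        include_interaction=False, response=self.response,
                        site_col=self.site_col, species_col=self.species_col)

    def env_only(self) -> "GlmmSpec":
        """Trait-free comparison model (trait slope and interaction zero):
        the species random intercept must then absorb every trait-driven
        difference, which is the total interspecies variance entering
        the variance-contribution statistic."""
        return GlmmSpec(self.env_name, self.trait_name, self.env_cols,
                        self.trait_col, self.interaction_cols,
                        include_interaction=False, include_trait=False,
                        response=self.response, site_col=self.site_col,
                        species_col=self.species_col)


#: Declared codings for binary categorical traits.
_TRAIT_CODING_ONE = {"mouth_position": "inferior"}


def _code_trait(traits: pd.DataFrame, species: list[str], trait_var: str):
    sub = traits[traits["trait"] == trait_var].set_index("species")
    missing = [sp for sp in species if sp not in sub.index]
    if missing:
        raise KeyError(f"trait {trait_var!r} missing for species {missing}")
    if (sub["trait_type"] == "quantitative").all():
        return {sp: float(sub.loc[sp, "value"]) for sp in species}
    levels = sorted(sub.loc[species, "value"].unique())
    if len(levels) > 2:
        raise DomainError(
            f"categorical trait {trait_var!r} has more than 2 levels")
    one = _TRAIT_CODING_ONE.get(trait_var, levels[-1] if len(levels) > 1
                                else levels[0])
    return {sp: float(sub.loc[sp, "value"] == one) for sp in species}


def build_trait_env_design(ds: Dataset, env_var: str, trait_var: str):
    """Long site x species table plus the model layout.

    One row per (site, species) with the count (0 where the species was
    absent), the environment value (numeric, or k-1 dummy columns for a
    categorical with the first sorted level as reference) and the species'
    trait value (numeric, or 0/1 for a binary categorical; mouth position
    codes inferior = 1).
    """
    if ds.sites is None or ds.counts is None or ds.traits is None:
        raise DomainError("dataset needs sites, counts and traits tables")
    if env_var not in ds.sites.columns:
        raise KeyError(f"environment variable {env_var!r} not in site table")
    species = ds.species()
    trait_map = _code_trait(ds.traits, species, trait_var)
    mat = counts_matrix(ds)

    rows = []
    for _, site in ds.sites.iterrows():
        for sp in species:
            rows.append({"site_id": site["site_id"], "species": sp,
                         "count": int(mat.loc[site["site_id"], sp]),
                         env_var: site[env_var],
                         trait_var: trait_map[sp]})
    long = pd.DataFrame(rows)

    env_raw = long[env_var]
    if pd.api.types.is_numeric_dtype(env_raw):
        env_cols = [env_var]
    else:
        levels = sorted(env_raw.unique())
        env_cols = []
        for lvl in levels[1:]:
            col = f"{env_var}[{lvl}]"
            long[col] = (env_raw == lvl).astype(float)
            env_cols.append(col)
    inter_cols = []
    for col in env_cols:
        icol = f"{col}:{trait_var}"
        long[icol] = long[col].astype(float) * long[trait_var]
        inter_cols.append(icol)

    spec = GlmmSpec(env_name=env_var, trait_name=trait_var,
                    env_cols=env_cols, trait_col=trait_var,
                    interaction_cols=inter_cols)
    return spec, long


# ---------------------------------------------------------------------------
# Laplace Poisson GLMM with crossed random intercepts

@dataclass
class ModelFit:
    """Laplace-ML fit of a Poisson GLMM with crossed random intercepts."""

    params: pd.Series
    se: pd.Series
    z: pd.Series
    p_values: pd.Series
    var_site: float
    var_species: float
    loglik: float
    aic: float
    df_model: int
    n_obs: int
    converged: bool
    wald_tests: dict = field(default_factory=dict)
    cov_params: pd.DataFrame | None = None
    spec: GlmmSpec | None = None
    label: str = ""


class _LaplaceGLMM:
    """Laplace-approximate likelihood machinery for one model design.

    The fixed effects are profiled: for given variance parameters the
    joint Poisson log-density is maximised over (beta, u) together by
    damped Newton (a penalised GLM fit), and the Laplace marginal
    log-likelihood evaluated at that mode.  The outer optimisation then
    runs over just the two log-SDs, which keeps the fit fast; the Wald
    covariance of beta is the fixed-effect block of the inverse joint
    information at the optimum.
    """

    def __init__(self, X, y, site_idx, species_idx, n_site, n_species):
        from scipy import sparse
        from scipy.special import gammaln

        self.X, self.y = X, y
        self.p = X.shape[1]
        self.n_site, self.n_species = n_site, n_species
        self.q = n_site + n_species
        n = X.shape[0]
        rows = np.arange(n)
        Z = sparse.csr_matrix(
            (np.ones(2 * n),
             (np.concatenate([rows, rows]),
              np.concatenate([site_idx, n_site + species_idx]))),
            shape=(n, self.q))
        self.M = sparse.hstack([sparse.csr_matrix(X), Z]).tocsr()
        self.Mt = self.M.T.tocsr()
        self.gl_y = float(gammaln(y + 1.0).sum())
        self.v = np.zeros(self.p + self.q)
        self.v[0] = np.log(max(y.mean(), 0.1))

    def _penalty(self, log_sd):
        s2_site, s2_sp = np.exp(2 * log_sd[0]), np.exp(2 * log_sd[1])
        dinv = np.concatenate([
            np.zeros(self.p),
            np.full(self.n_site, 1.0 / s2_site),
            np.full(self.n_species, 1.0 / s2_sp),
        ])
        const = (0.5 * self.n_site * np.log(2 * np.pi * s2_site)
                 + 0.5 * self.n_species * np.log(2 * np.pi * s2_sp))
        return dinv, const

    def _joint(self, v, dinv, const):
        eta = np.clip(self.M @ v, -30, 30)
        return (self.y @ eta - np.exp(eta).sum() - self.gl_y
                - 0.5 * (dinv * v**2).sum() - const)

    def profiled_loglik(self, log_sd, max_newton=100):
        """Laplace marginal log-likelihood profiled over (beta, u)."""
        dinv, const = self._penalty(log_sd)
        v = self.v.copy()
        f = self._joint(v, dinv, const)
        H = None
        for _ in range(max_newton):
            eta = np.clip(self.M @ v, -30, 30)
            mu = np.exp(eta)
            grad = self.Mt @ (self.y - mu) - dinv * v
            H = (self.Mt.multiply(mu) @ self.M).toarray()
            H[np.diag_indices_from(H)] += dinv
            if np.abs(grad).max() < 1e-9:
                break
            try:
                delta = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                return -np.inf, v, None
            t = 1.0
            for _ in range(30):
                f_new = self._joint(v + t * delta, dinv, const)
                if f_new >= f - 1e-12:
                    break
                t *= 0.5
            v = v + t * delta
            f = f_new
        self.v = v
        H_uu = H[self.p:, self.p:]
        sign, logdet = np.linalg.slogdet(H_uu)
        if sign <= 0:
            return -np.inf, v, H
        ll = f + 0.5 * self.q * np.log(2 * np.pi) - 0.5 * logdet
        return ll, v, H

    def fit(self, max_iter=200, tol=1e-8):
        """Optimise the two variance parameters; returns the full state."""
        def negll(log_sd):
            ll, _, _ = self.profiled_loglik(log_sd)
            return -ll

        # the two variance parameters need only moderate precision (their
        # SEs are not reported); a wider FD step keeps the profiled-
        # likelihood noise from the inner solver out of the gradient
        res = optimize.minimize(
            negll, np.array([np.log(0.3), np.log(0.3)]), method="L-BFGS-B",
            bounds=[(-6.0, 3.0)] * 2,
            options={"maxiter": max_iter, "ftol": 1e-9, "gtol": 1e-6,
                     "eps": 1e-5})
        ll, v, H = self.profiled_loglik(res.x)
        cov_beta = None
        if H is not None:
            try:
                cov_beta = np.linalg.inv(H)[:self.p, :self.p]
            except np.linalg.LinAlgError:
                pass
        return {
            "log_sd": res.x, "loglik": float(ll), "beta": v[:self.p],
            "u": v[self.p:], "cov_beta": cov_beta,
            "converged": bool(res.success) and np.isfinite(ll)
            and cov_beta is not None,
        }


def _prepare_indices(spec: GlmmSpec, data: pd.DataFrame):
    sites = pd.Categorical(data[spec.site_col])
    species = pd.Categorical(data[spec.species_col])
    return (sites.codes.astype(int), species.codes.astype(int),
            len(sites.categories), len(species.categories))


def fit_trait_env_glmm(spec: GlmmSpec, data: pd.DataFrame,
                       max_iter: int = 200, tol: float = 1e-8,
                       label: str = "") -> ModelFit:
    """Fit the Poisson GLMM by Laplace-approximate maximum likelihood.

    Fixed effects: intercept, environment, trait and (optionally) their
    interaction; crossed random intercepts for sites and species, with
    the two variance components estimated on the log-SD scale.  Wald z
    per coefficient, and a Wald chi-squared over the dummy block of any
    multi-level environment term.  A fit that fails to converge is
    returned with ``converged=False`` rather than silently trusted.
    """
    fixed = spec.fixed_columns()
    n_obs = len(data)
    X = np.column_stack([np.ones(n_obs)]
                        + [data[c].to_numpy(float) for c in fixed])
    names = ["intercept"] + fixed
    y = data[spec.response].to_numpy(float)
    site_idx, species_idx, n_site, n_species = _prepare_indices(spec, data)
    if n_site < 2 or n_species < 2:
        raise DomainError("need at least 2 sites and 2 species")

    engine = _LaplaceGLMM(X, y, site_idx, species_idx, n_site, n_species)
    state = engine.fit(max_iter=max_iter, tol=tol)
    p = X.shape[1]
    theta = state["beta"]
    loglik = state["loglik"]
    converged = state["converged"]

    cov = state["cov_beta"]
    if cov is None:
        cov = np.full((p, p), np.nan)
    se_all = np.sqrt(np.clip(np.diag(cov), 0, None))
    params = pd.Series(theta, index=names)
    se = pd.Series(se_all, index=names)
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = params / se
    pvals = 2 * stats.norm.sf(np.abs(zval))

    wald = {}
    for term, cols in (("env", spec.env_cols),
                       ("interaction", spec.interaction_cols
                        if spec.include_interaction else [])):
        if not cols:
            continue
        idx = [names.index(c) for c in cols]
        b = theta[idx]
        V = cov[np.ix_(idx, idx)]
        try:
            chi2 = float(b @ np.linalg.solve(V, b))
            wald[term] = {"chi2": chi2, "df": len(idx),
                          "p": float(stats.chi2.sf(chi2, len(idx)))}
        except np.linalg.LinAlgError:
            pass

    df_model = p + 2
    fit = ModelFit(
        params=params, se=se, z=pd.Series(zval, index=names),
        p_values=pd.Series(pvals, index=names),
        var_site=float(np.exp(2 * state["log_sd"][0])),
        var_species=float(np.exp(2 * state["log_sd"][1])),
        loglik=float(loglik), aic=float(-2 * loglik + 2 * df_model),
        df_model=df_model, n_obs=n_obs, converged=converged,
        wald_tests=wald,
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        spec=spec, label=label or f"{spec.env_name} x {spec.trait_name}"
              + ("" if spec.include_interaction else " (no interaction)"),
    )
    if not converged:
        warnings.warn(f"GLMM {fit.label!r} did not converge")
    return fit


def fit_null_glmm(data: pd.DataFrame, spec: GlmmSpec,
                  label: str = "null (random effects only)") -> ModelFit:
    """Intercept-only Poisson GLMM with the same crossed random effects."""
    n_obs = len(data)
    X = np.ones((n_obs, 1))
    y = data[spec.response].to_numpy(float)
    site_idx, species_idx, n_site, n_species = _prepare_indices(spec, data)
    engine = _LaplaceGLMM(X, y, site_idx, species_idx, n_site, n_species)
    state = engine.fit()
    loglik = state["loglik"]
    df_model = 3
    cov = state["cov_beta"]
    se0 = float(np.sqrt(cov[0, 0])) if cov is not None else np.nan
    return ModelFit(
        params=pd.Series(state["beta"], index=["intercept"]),
        se=pd.Series([se0], index=["intercept"]),
        z=pd.Series([state["beta"][0] / se0 if se0 else np.nan],
                    index=["intercept"]),
        p_values=pd.Series([np.nan], index=["intercept"]),
        var_site=float(np.exp(2 * state["log_sd"][0])),
        var_species=float(np.exp(2 * state["log_sd"][1])),
        loglik=float(loglik), aic=float(-2 * loglik + 2 * df_model),
        df_model=df_model, n_obs=n_obs, converged=state["converged"],
        spec=spec, label=label,
    )


# ---------------------------------------------------------------------------
# model comparison

def compare_models(fits: list[ModelFit], null_fit: ModelFit) -> pd.DataFrame:
    """AIC table with Akaike weights and LRTs against a nested null.

    w_i = exp(-Delta_i/2) / sum_m exp(-Delta_m/2); the LRT statistic is
    2 (loglik_full - loglik_null) on df = difference in parameter count.
    A model with fewer parameters than the null gets an AIC-only row.
    """
    if not fits:
        raise ContractError("need at least one fitted model")
    rows = []
    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    weights = np.exp(-delta / 2)
    weights = weights / weights.sum()
    for f, d_aic, w in zip(fits, delta, weights):
        row = {"model": f.label, "df": f.df_model, "AIC": f.aic,
               "dAIC": float(d_aic), "weight": float(w),
               "loglik": f.loglik, "deviance": -2 * f.loglik}
        if f.df_model > null_fit.df_model:
            chi2 = max(2 * (f.loglik - null_fit.loglik), 0.0)
            df = f.df_model - null_fit.df_model
            row.update(chi2=float(chi2), chi2_df=df,
                       p=float(stats.chi2.sf(chi2, df)))
        else:
            row.update(chi2=np.nan, chi2_df=np.nan, p=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def lrt(full: ModelFit, null: ModelFit):
    """Likelihood ratio test of nested Laplace fits."""
    if full.df_model <= null.df_model:
        raise ContractError("LRT requires the full model to nest the null")
    chi2 = max(2 * (full.loglik - null.loglik), 0.0)
    df = full.df_model - null.df_model
    return float(chi2), df, float(stats.chi2.sf(chi2, df))


def c_beta(var_resid_with_interaction: float,
           var_total_without: float) -> float:
    """Proportional reduction in between-species variance from the
    trait x environment interaction: c_beta = 1 - var_resid / var_total.

    ``var_resid_with_interaction`` is the species-level random-effect
    variance of the model including the interaction, ``var_total_without``
    that of the model without it.  Negative values (interaction inflates
    the variance) are reported with a warning rather than clipped.
    """
    if var_total_without <= 0:
        raise DomainError("total variance must be strictly positive")
    if var_resid_with_interaction < 0:
        raise DomainError("variances must be non-negative")
    value = 1.0 - var_resid_with_interaction / var_total_without
    if value < 0:
        warnings.warn("interaction increased the between-species variance "
                      f"(c_beta = {value:.3f})")
    return float(value)
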