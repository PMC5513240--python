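"""Isotopic trophic-niche metrics on bivariate (d13C, d15N) data.

Community-level Layman metrics summarise the geometry of a species' point
cloud in isotope space: the d13C range (CR) tracks breadth of basal carbon
sources, the d15N range (NR) trophic length, mean distance to centroid
(CD) average trophic diversity, and the nearest-neighbour statistics
(MNND, SDNND) trophic redundancy.  Niche size is the standard ellipse
area SEA = pi * sqrt(det(Sigma)) of the sample covariance, with the
small-sample correction SEAc = SEA * (n-1)/(n-2).  Uncertainty comes from
a conjugate Normal-Inverse-Wishart posterior on (mu, Sigma); the niche
region N_R at level alpha is the ellipse containing an individual with
probability alpha under the bivariate-normal model, and the directional
overlap of species A onto B is the posterior probability that an
individual drawn from A's distribution falls inside B's N_R.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import ConvexHull, QhullError

from ._errors import ContractError, DegenerateDataError, DomainError

__all__ = [
    "IsotopePointSet", "LaymanMetrics", "EllipseFit", "PosteriorDraws",
    "NicheRegion", "OverlapPosterior",
    "layman_metrics", "fit_standard_ellipse", "posterior_mu_sigma",
    "sea_posterior", "niche_region", "overlap_prob", "bootstrap_metric",
    "point_sets_from_table",
]


@dataclass
class IsotopePointSet:
    """A labelled cloud of (d13C, d15N) points, per mil."""

    group: str
    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise DomainError("points must be an (n, 2) array")
        if not np.isfinite(self.points).all():
            raise DomainError("isotope values must be finite")

    @property
    def n(self) -> int:
        return self.points.shape[0]


def point_sets_from_table(isotopes, groups=None) -> dict[str, IsotopePointSet]:
    """Split an isotopes table into per-group point sets."""
    out = {}
    for g, sub in isotopes.groupby("group"):
        if groups is not None and g not in groups:
            continue
        out[g] = IsotopePointSet(g, sub[["d13C", "d15N"]].to_numpy(float))
    return out


# ---------------------------------------------------------------------------
# Layman metrics

@dataclass
class LaymanMetrics:
    CR: float
    NR: float
    CD: float
    MNND: float
    SDNND: float
    hull_area: float


def _nearest_neighbour_distances(pts: np.ndarray) -> np.ndarray:
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def layman_metrics(ps: IsotopePointSet) -> LaymanMetrics:
    """Community metrics of an isotopic point cloud (all in per mil;
    hull area in per-mil squared)."""
    pts = ps.points
    if ps.n < 2:
        raise DomainError("Layman metrics require at least 2 points")
    centroid = pts.mean(axis=0)
    cd = float(np.sqrt(((pts - centroid) ** 2).sum(axis=1)).mean())
    nnd = _nearest_neighbour_distances(pts)
    mnnd = float(nnd.mean())
    sdnnd = float(nnd.std(ddof=1)) if ps.n > 1 else 0.0
    hull_area = 0.0
    if ps.n >= 3:
        try:
            hull_area = float(ConvexHull(pts).volume)
        except QhullError:
            warnings.warn("points are collinear; hull area set to 0")
    return LaymanMetrics(
        CR=float(pts[:, 0].max() - pts[:, 0].min()),
        NR=float(pts[:, 1].max() - pts[:, 1].min()),
        CD=cd, MNND=mnnd, SDNND=sdnnd, hull_area=hull_area,
    )


# ---------------------------------------------------------------------------
# standard ellipse

@dataclass
class EllipseFit:
    mean: np.ndarray
    cov: np.ndarray
    n: int
    SEA: float
    SEAc: float


def fit_standard_ellipse(ps: IsotopePointSet) -> EllipseFit:
    """Standard ellipse of a bivariate sample.

    SEA = pi * sqrt(det(S)) with S the unbiased sample covariance;
    SEAc = SEA * (n-1)/(n-2) corrects the small-sample bias.
    """
    if ps.n < 3:
        raise DomainError("standard ellipse requires n >= 3")
    mean = ps.points.mean(axis=0)
    cov = np.cov(ps.points, rowvar=False, ddof=1)
    det = float(np.linalg.det(cov))
    if det <= 0:
        raise DegenerateDataError("sample covariance is singular")
    sea = float(np.pi * np.sqrt(det))
    return EllipseFit(mean=mean, cov=cov, n=ps.n, SEA=sea,
                      SEAc=sea * (ps.n - 1) / (ps.n - 2))


# ---------------------------------------------------------------------------
# conjugate posterior on (mu, Sigma)

@dataclass
class PosteriorDraws:
    """Joint posterior draws of the bivariate-normal parameters."""

    mu: np.ndarray        # (n_draws, 2)
    sigma: np.ndarray     # (n_draws, 2, 2)
    n_draws: int
    seed: int | None = None
    prior: dict = field(default_factory=dict)

    @classmethod
    def from_fixed(cls, mu, sigma, n_draws: int = 1) -> "PosteriorDraws":
        """Plug-in 'posterior' with every draw at a fixed (mu, Sigma);
        useful for closed-form checks of region/overlap definitions."""
        mu = np.tile(np.asarray(mu, float), (n_draws, 1))
        sigma = np.tile(np.asarray(sigma, float), (n_draws, 1, 1))
        return cls(mu=mu, sigma=sigma, n_draws=n_draws)


def posterior_mu_sigma(ps: IsotopePointSet, n_draws: int = 1000,
                       seed: int | None = None,
                       kappa0: float = 1e-3, nu0: float = 3.0,
                       psi0: np.ndarray | None = None,
                       mu0: np.ndarray | None = None) -> PosteriorDraws:
    """Sample the Normal-Inverse-Wishart posterior of (mu, Sigma).

    The default prior is vague and scale-adapted: mu0 = sample mean with
    prior weight kappa0 = 1e-3 observations, nu0 = 3 (= dim + 1) degrees
    of freedom, Psi0 = nu0 * sample covariance.  Conjugacy gives exact
    draws, so no MCMC diagnostics are needed.
    """
    if ps.n < 3:
        raise DomainError("posterior requires n >= 3")
    if n_draws < 1:
        raise ContractError("n_draws must be >= 1")
    x = ps.points
    n = ps.n
    xbar = x.mean(axis=0)
    S = (x - xbar).T @ (x - xbar)
    if mu0 is None:
        mu0 = xbar
    if psi0 is None:
        psi0 = nu0 * np.cov(x, rowvar=False, ddof=1)
    kappa_n = kappa0 + n
    nu_n = nu0 + n
    mu_n = (kappa0 * np.asarray(mu0, float) + n * xbar) / kappa_n
    dev = (xbar - mu0)[:, None]
    psi_n = np.asarray(psi0, float) + S + (kappa0 * n / kappa_n) * (dev @ dev.T)

    rng = np.random.default_rng(seed)
    sigma = stats.invwishart(df=nu_n, scale=psi_n).rvs(
        size=n_draws, random_state=rng)
    sigma = sigma.reshape(n_draws, 2, 2)
    chol = np.linalg.cholesky(sigma / kappa_n)
    mu = mu_n + np.einsum("dij,dj->di", chol, rng.standard_normal((n_draws, 2)))
    return PosteriorDraws(mu=mu, sigma=sigma, n_draws=n_draws, seed=seed,
                          prior={"kappa0": kappa0, "nu0": nu0})


def sea_posterior(post: PosteriorDraws,
                  levels: tuple[float, ...] = (0.5, 0.75, 0.95)) -> dict:
    """Posterior of the standard ellipse area (SEA_B).

    Returns the per-draw SEA values, equal-tailed credible intervals at the
    requested levels, the posterior mean and a kernel-density mode.
    """
    if post.n_draws < 100:
        raise ContractError("SEA_B needs at least 100 posterior draws")
    det = np.linalg.det(post.sigma)
    draws = np.pi * np.sqrt(det)
    intervals = {
        lvl: tuple(np.quantile(draws, [(1 - lvl) / 2, 1 - (1 - lvl) / 2]))
        for lvl in levels
    }
    if np.ptp(draws) > 0:
        kde = stats.gaussian_kde(draws)
        grid = np.linspace(draws.min(), draws.max(), 512)
        mode = float(grid[np.argmax(kde(grid))])
    else:
        mode = float(draws[0])
    return {"draws": draws, "mean": float(draws.mean()), "mode": mode,
            "intervals": intervals}


# ---------------------------------------------------------------------------
# niche region and directional overlap

@dataclass
class NicheRegion:
    """Elliptical region holding an individual with probability alpha."""

    mu: np.ndarray
    sigma: np.ndarray
    alpha: float
    q: float                 # chi-squared(2) quantile at alpha
    semi_axes: np.ndarray    # lengths of the two ellipse semi-axes
    orientation: float       # angle (radians) of the major axis

    def contains(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, float))
        dev = z - self.mu
        m = np.einsum("ni,ij,nj->n", dev, np.linalg.inv(self.sigma), dev)
        return m <= self.q


def niche_region(mu: np.ndarray, sigma: np.ndarray,
                 alpha: float = 0.95) -> NicheRegion:
    """The alpha-level niche region {z : (z-mu)' Sigma^-1 (z-mu) <= q},
    q the chi-squared(2) quantile at alpha."""
    if not 0 < alpha < 1:
        raise DomainError("alpha must be in (0, 1)")
    sigma = np.asarray(sigma, float)
    evals, evecs = np.linalg.eigh(sigma)
    if np.any(evals <= 0):
        raise DomainError("sigma must be symmetric positive-definite")
    q = float(stats.chi2.ppf(alpha, df=2))
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    return NicheRegion(
        mu=np.asarray(mu, float), sigma=sigma, alpha=alpha, q=q,
        semi_axes=np.sqrt(evals * q),
        orientation=float(np.arctan2(evecs[1, 0], evecs[0, 0])),
    )


@dataclass
class OverlapPosterior:
    """Posterior of the directional overlap probability of A onto B."""

    direction: tuple[str, str]
    alpha: float
    draws: np.ndarray
    mean: float
    ci95: tuple[float, float]


def overlap_prob(post_a: PosteriorDraws, post_b: PosteriorDraws,
                 alpha: float = 0.95, n_mc: int = 10_000,
                 seed: int | None = None,
                 direction: tuple[str, str] = ("A", "B")) -> OverlapPosterior:
    """P(individual of A falls in B's niche region), posterior over draws.

    Draws are paired by index; for each pair, n_mc points are sampled from
    N(mu_A, Sigma_A) and the fraction inside B's alpha-region recorded.
    The overlap is directional: A onto B generally differs from B onto A.
    """
    if not 0 < alpha < 1:
        raise DomainError("alpha must be in (0, 1)")
    if n_mc < 1000:
        raise ContractError("n_mc must be at least 1000")
    if post_a.n_draws != post_b.n_draws:
        raise ContractError("posterior draw counts must match (paired by index)")
    rng = np.random.default_rng(seed)
    q = stats.chi2.ppf(alpha, df=2)
    draws = np.empty(post_a.n_draws)
    for t in range(post_a.n_draws):
        la = np.linalg.cholesky(post_a.sigma[t])
        z = post_a.mu[t] + rng.standard_normal((n_mc, 2)) @ la.T
        dev = z - post_b.mu[t]
        sb_inv = np.linalg.inv(post_b.sigma[t])
        m = np.einsum("ni,ij,nj->n", dev, sb_inv, dev)
        draws[t] = (m <= q).mean()
    return OverlapPosterior(
        direction=direction, alpha=alpha, draws=draws,
        mean=float(draws.mean()),
        ci95=tuple(np.quantile(draws, [0.025, 0.975])),
    )


# ---------------------------------------------------------------------------
# bootstrap

_METRICS = {
    "CR": lambda ps: layman_metrics(ps).CR,
    "NR": lambda ps: layman_metrics(ps).NR,
    "CD": lambda ps: layman_metrics(ps).CD,
    "MNND": lambda ps: layman_metrics(ps).MNND,
    "SDNND": lambda ps: layman_metrics(ps).SDNND,
    "hull_area": lambda ps: layman_metrics(ps).hull_area,
    "SEA": lambda ps: fit_standard_ellipse(ps).SEA,
    "SEAc": lambda ps: fit_standard_ellipse(ps).SEAc,
}


def bootstrap_metric(ps: IsotopePointSet, metric: str, n_boot: int = 1000,
                     seed: int | None = None):
    """Nonparametric bootstrap of one niche metric.

    Returns (point estimate, bootstrap SD, percentile 95% CI).  Resamples
    that are degenerate for the metric (e.g. a singular covariance for
    SEA) are recorded as NaN and excluded from the summaries.
    """
    if metric not in _METRICS:
        raise KeyError(
            f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    if ps.n < 2:
        raise DomainError("bootstrap requires n >= 2")
    fn = _METRICS[metric]
    estimate = fn(ps)
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, ps.n, size=ps.n)
        sub = IsotopePointSet(ps.group, ps.points[idx])
        try:
            vals[b] = fn(sub)
        except (DegenerateDataError, DomainError):
            vals[b] = np.nan
    ok = vals[~np.isnan(vals)]
    sd = float(ok.std(ddof=1)) if ok.size > 1 else 0.0
    ci = tuple(np.quantile(ok, [0.025, 0.975])) if ok.size else (np.nan, np.nan)
    return estimate, sd, ci
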