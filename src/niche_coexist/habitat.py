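"""Unified habitat niche overlap across mixed data types.

Different microhabitat axes carry different data types: occurrence in a
two-state mesohabitat (pool/riffle) is Bernoulli, association with
substratum classes is electivity data (use relative to availability,
summarised by Manly's alpha), and abundance along the depth gradient is
count data (modelled as a nonparametric Poisson mixture, the count
analogue of a kernel density estimate).  Each axis yields a niche overlap
(NO) in [0, 1]; the unified NO between two species is the arithmetic mean
of the axis NOs.  Significance is assessed against a permutation null in
which species labels are reassigned to individual capture records, which
preserves each species' total catch while destroying any association with
microhabitat (H0: no niche differentiation; small p means overlap is
lower than expected by chance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from ._errors import ContractError, DegenerateDataError, DomainError
from .io import Dataset, SUBSTRATUM_LEVELS, counts_matrix

__all__ = [
    "AxisSpec", "PoissonMixture", "OverlapResult",
    "overlap_binary", "manly_alpha", "overlap_electivity",
    "fit_npmle_poisson_mixture", "overlap_pmf", "unified_overlap",
    "permutation_test", "default_axes",
]


# ---------------------------------------------------------------------------
# axis specifications

@dataclass(frozen=True)
class AxisSpec:
    """One niche axis: a name, its data type, and how it maps onto a Dataset.

    ``data_type`` is one of ``binary`` (two-state occurrence), ``electivity``
    (categorical use vs availability via Manly's alpha) or ``count``
    (abundance along a gradient).  ``source`` names the site-table column
    the axis reads ("habitat_type", "substratum", ...); count axes read the
    per-site catch directly.  ``mode`` selects an alternative overlap
    reading where more than one is defensible: for binary axes
    ``"joint"`` (default, joint probability of co-occurrence and
    co-absence) or ``"schoener"`` (1 - |p_i - p_j|); for count axes
    ``"npmle"`` (default) or ``"depth_weighted"`` (count-weighted
    depth-class histogram compared by Schoener overlap).
    """

    name: str
    data_type: str
    source: str = ""
    mode: str = "default"

    def __post_init__(self):
        if self.data_type not in ("binary", "electivity", "count"):
            raise DomainError(f"unknown axis data_type {self.data_type!r}")


def default_axes() -> list[AxisSpec]:
    """The three microhabitat axes: habitat type, substratum, depth."""
    return [
        AxisSpec("habitat", "binary", source="habitat_type"),
        AxisSpec("substratum", "electivity", source="substratum"),
        AxisSpec("depth", "count", source="depth"),
    ]


# ---------------------------------------------------------------------------
# per-axis overlap primitives

def overlap_binary(occ_i: np.ndarray, occ_j: np.ndarray,
                   mode: str = "joint") -> float:
    """NO along a two-state axis from two binary vectors.

    With p the fraction of ones in each vector (the Bernoulli MLE),
    ``joint`` returns p_i p_j + (1-p_i)(1-p_j): the probability that two
    independent individuals fall in the same state.  ``schoener`` returns
    1 - |p_i - p_j|.
    """
    occ_i = np.asarray(occ_i, dtype=float)
    occ_j = np.asarray(occ_j, dtype=float)
    if occ_i.size == 0 or occ_j.size == 0:
        raise DomainError("binary axis requires non-empty vectors")
    p_i, p_j = occ_i.mean(), occ_j.mean()
    if mode == "joint":
        return float(p_i * p_j + (1.0 - p_i) * (1.0 - p_j))
    if mode == "schoener":
        return float(1.0 - abs(p_i - p_j))
    raise DomainError(f"unknown binary overlap mode {mode!r}")


def manly_alpha(use_props: np.ndarray, avail_props: np.ndarray) -> np.ndarray:
    """Manly's alpha electivity index over K resource categories.

    alpha_k = (use_k / avail_k) / sum_m (use_m / avail_m).  Categories with
    zero availability must have zero use; the result is a simplex.  Values
    above 1/K indicate selection, below 1/K avoidance.
    """
    use = np.asarray(use_props, dtype=float)
    avail = np.asarray(avail_props, dtype=float)
    if use.shape != avail.shape:
        raise DomainError("use and availability vectors must have equal length")
    if np.any((avail <= 0) & (use > 0)):
        raise DomainError("category used but unavailable (avail = 0, use > 0)")
    if not np.any(use > 0):
        raise DegenerateDataError("all use proportions zero: electivity undefined")
    ratio = np.zeros_like(use)
    pos = avail > 0
    ratio[pos] = use[pos] / avail[pos]
    return ratio / ratio.sum()


def overlap_electivity(alpha_i: np.ndarray, alpha_j: np.ndarray) -> float:
    """Schoener-type overlap of two electivity simplexes:
    NO = 1 - 0.5 * sum_k |alpha_ik - alpha_jk|."""
    alpha_i = np.asarray(alpha_i, dtype=float)
    alpha_j = np.asarray(alpha_j, dtype=float)
    if alpha_i.shape != alpha_j.shape:
        raise DomainError("electivity vectors must have equal length")
    return float(1.0 - 0.5 * np.abs(alpha_i - alpha_j).sum())


# ---------------------------------------------------------------------------
# NPMLE Poisson mixture (count axis)

@dataclass
class PoissonMixture:
    """Finite Poisson mixture on a fixed rate grid.

    ``support`` holds the rates (strictly increasing, >= 0) and ``weights``
    the mixing proportions (a simplex).  A zero rate contributes a point
    mass at zero counts.
    """

    support: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.support = np.asarray(self.support, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.support < 0):
            raise DomainError("Poisson rates must be non-negative")
        if np.any(np.diff(self.support) <= 0):
            raise DomainError("support must be strictly increasing")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise DomainError("mixture weights must sum to 1")

    def pmf(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return _poisson_pmf_matrix(self.support, x).T @ self.weights

    def log_likelihood(self, counts: np.ndarray) -> float:
        p = self.pmf(np.asarray(counts, dtype=float))
        return float(np.sum(np.log(np.clip(p, 1e-300, None))))


def _poisson_pmf_matrix(lam: np.ndarray, x: np.ndarray) -> np.ndarray:
    """pmf matrix P[k, u] = Pois(x_u | lam_k); lam = 0 handled as a point
    mass at zero."""
    lam = np.asarray(lam, dtype=float)[:, None]
    x = np.asarray(x, dtype=float)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = x * np.log(lam) - lam - gammaln(x + 1.0)
    out = np.exp(logp)
    zero = (lam[:, 0] == 0)
    if zero.any():
        out[zero, :] = (x[0] == 0).astype(float)
    return out


def fit_npmle_poisson_mixture(counts: np.ndarray,
                              grid_step: float = 0.1,
                              tol: float = 1e-8,
                              max_iter: int = 2000,
                              prune: float = 1e-8) -> PoissonMixture:
    """Nonparametric MLE of a count distribution as a Poisson mixture.

    Candidate rates live on the fixed grid {0, grid_step, ...,
    max(count)+3*sqrt(max)} plus the sample mean; the optimal mixture is
    found by support selection (grid points enter while the likelihood
    gradient exceeds its stationary bound n) with the weight sub-problem
    solved to high precision on each active support.  The result is the
    count analogue of a kernel density estimate, and its log-likelihood
    dominates the single Poisson fitted at the sample mean.
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise DomainError("need at least one count")
    if np.any(counts < 0) or np.any(counts != np.floor(counts)):
        raise DomainError("counts must be non-negative integers")
    counts = counts.astype(float)
    cmax = counts.max()
    if cmax == 0:
        return PoissonMixture(np.array([0.0]), np.array([1.0]))

    hi = cmax + 3.0 * np.sqrt(cmax)
    grid = np.arange(0.0, hi + grid_step / 2, grid_step)
    # include the sample mean so the single-Poisson MLE is in the support
    mean = counts.mean()
    if np.abs(grid - mean).min() > 1e-12:
        grid = np.sort(np.append(grid, mean))
    uniq, mult = np.unique(counts, return_counts=True)
    P = _poisson_pmf_matrix(grid, uniq)          # K x U
    n = counts.size

    # support-selection NPMLE: the optimum puts mass on few grid points,
    # so solve exactly on a growing active support and add the grid point
    # with the largest likelihood gradient until optimality (grad <= n).
    active = np.unique(np.searchsorted(grid, np.append(uniq, mean)).clip(
        0, grid.size - 1))
    w = np.full(active.size, 1.0 / active.size)

    for _ in range(50):
        w, active = _solve_active_weights(P, active, w, mult, n, max_iter)
        dens = np.clip(w @ P[active], 1e-300, None)
        grad = P @ (mult / dens)           # stationarity: grad <= n
        k_new = int(np.argmax(grad))
        if grad[k_new] <= n * (1 + tol) or k_new in active:
            break
        # add up to three well-separated violating grid points per round
        order = np.argsort(grad)[::-1]
        new_pts = []
        for k in order:
            if grad[k] <= n * (1 + tol) or len(new_pts) == 3:
                break
            if k not in active and all(abs(k - m) > 4 for m in new_pts):
                new_pts.append(int(k))
        if not new_pts:
            break
        eps = 1e-3
        active = np.sort(np.append(active, new_pts))
        w_full = np.zeros(active.size)
        old = ~np.isin(active, new_pts)
        w_full[old] = w * (1 - eps * len(new_pts))
        w_full[~old] = eps
        w = w_full

    keep = w > prune
    w, support = w[keep], grid[active][keep]
    w = w / w.sum()
    return PoissonMixture(support, w)


def _solve_active_weights(P, active, w, mult, n, max_iter):
    """Maximise the mixture log-likelihood over weights on a fixed support.

    The simplex constraint is absorbed by a softmax reparameterisation and
    the smooth problem solved by L-BFGS, which is robust even when
    neighbouring grid rates make the likelihood nearly collinear; support
    points driven to negligible weight are dropped.
    """
    from scipy.optimize import fmin_l_bfgs_b

    if active.size == 1:
        return np.array([1.0]), active
    Pa = P[active]

    def negll_grad(z):
        z = z - z.max()
        e = np.exp(z)
        w = e / e.sum()
        dens = np.clip(w @ Pa, 1e-300, None)
        ll = float(mult @ np.log(dens))
        g = Pa @ (mult / dens)
        return -ll, -(w * (g - n))

    z0 = np.log(np.clip(w, 1e-12, None))
    zhat, _, _ = fmin_l_bfgs_b(negll_grad, z0, maxiter=max_iter,
                               factr=1e3, pgtol=1e-8)
    z = zhat - zhat.max()
    w = np.exp(z)
    w /= w.sum()
    keep = w > 1e-12
    if not keep.all():
        active, w = active[keep], w[keep]
        w = w / w.sum()
    return w, active


def overlap_pmf(f_i: PoissonMixture, f_j: PoissonMixture,
                tail: float = 1e-8) -> float:
    """Overlap of two count distributions:
    NO = sum_x min(f_i(x), f_j(x)), truncated where both tails are < tail."""
    lam_max = max(f_i.support.max(initial=0.0), f_j.support.max(initial=0.0))
    x_hi = int(np.ceil(lam_max + 12.0 * np.sqrt(lam_max + 1.0) + 25))
    x = np.arange(0, x_hi + 1)
    no = float(np.minimum(f_i.pmf(x), f_j.pmf(x)).sum())
    return min(max(no, 0.0), 1.0)


def unified_overlap(per_axis: dict[str, float]) -> float:
    """Unified NO: arithmetic mean of the per-axis overlaps."""
    if not per_axis:
        raise DomainError("need at least one axis")
    return float(np.mean(list(per_axis.values())))


# ---------------------------------------------------------------------------
# axis evaluation on a dataset

def _depth_class_histogram(depths: np.ndarray, counts: np.ndarray,
                           edges: np.ndarray) -> np.ndarray:
    hist, _ = np.histogram(depths, bins=edges, weights=counts)
    total = hist.sum()
    if total == 0:
        raise DegenerateDataError("species has zero total catch")
    return hist / total


def _axis_no(axis: AxisSpec, sites, counts_i: np.ndarray,
             counts_j: np.ndarray, npmle_kwargs: dict) -> float:
    """NO along one axis for a species pair given per-site count vectors."""
    occ_i = counts_i > 0
    occ_j = counts_j > 0
    if axis.data_type == "binary":
        states = (sites[axis.source or "habitat_type"] == "pool").to_numpy()
        if not occ_i.any() or not occ_j.any():
            raise DegenerateDataError("species occupies no sites")
        mode = "joint" if axis.mode == "default" else axis.mode
        return overlap_binary(states[occ_i], states[occ_j], mode=mode)
    if axis.data_type == "electivity":
        cats = sites[axis.source or "substratum"]
        levels = [l for l in SUBSTRATUM_LEVELS if (cats == l).any()] \
            if axis.source in ("", "substratum") else sorted(cats.unique())
        avail = np.array([(cats == l).mean() for l in levels])
        use_i = np.array([((cats == l) & occ_i).sum() for l in levels],
                         dtype=float)
        use_j = np.array([((cats == l) & occ_j).sum() for l in levels],
                         dtype=float)
        a_i = manly_alpha(use_i / max(use_i.sum(), 1.0), avail)
        a_j = manly_alpha(use_j / max(use_j.sum(), 1.0), avail)
        return overlap_electivity(a_i, a_j)
    # count axis
    if axis.mode == "depth_weighted":
        depths = sites[axis.source or "depth"].to_numpy(float)
        edges = np.quantile(depths, np.linspace(0, 1, 6))
        edges[0], edges[-1] = -np.inf, np.inf
        h_i = _depth_class_histogram(depths, counts_i.astype(float), edges)
        h_j = _depth_class_histogram(depths, counts_j.astype(float), edges)
        return float(1.0 - 0.5 * np.abs(h_i - h_j).sum())
    f_i = fit_npmle_poisson_mixture(counts_i, **npmle_kwargs)
    f_j = fit_npmle_poisson_mixture(counts_j, **npmle_kwargs)
    return overlap_pmf(f_i, f_j)


def axis_overlaps(ds: Dataset, axes: list[AxisSpec], species_i: str,
                  species_j: str, npmle_kwargs: dict | None = None
                  ) -> dict[str, float]:
    """Per-axis NO for one species pair on observed data."""
    mat = counts_matrix(ds)
    return _axis_overlaps_from_vectors(
        ds.sites, axes, mat[species_i].to_numpy(), mat[species_j].to_numpy(),
        npmle_kwargs or {})


def _axis_overlaps_from_vectors(sites, axes, ci, cj, npmle_kwargs):
    return {ax.name: _axis_no(ax, sites, ci, cj, npmle_kwargs) for ax in axes}


# ---------------------------------------------------------------------------
# permutation null

@dataclass
class OverlapResult:
    """Observed overlap for a species pair plus its permutation null."""

    species_pair: tuple[str, str]
    per_axis_no: dict[str, float]
    unified_no: float
    null_distribution: np.ndarray
    p_value: float
    per_axis_p: dict[str, float] = field(default_factory=dict)
    n_perm: int = 0


def permutation_test(ds: Dataset, axes: list[AxisSpec],
                     pair: tuple[str, str], n_perm: int = 1000,
                     seed: int | None = None,
                     unit: str = "individual",
                     npmle_kwargs: dict | None = None) -> OverlapResult:
    """Permutation test of niche overlap between two species.

    The null reassigns species labels to individual capture records
    (each fish keeps its site; each species keeps its total catch) and
    recomputes every axis NO and the unified NO.  ``unit="site"`` instead
    swaps whole site rows between the species.  p-values are lower-tail
    with the add-one correction: p = (1 + #{null <= observed}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ContractError("n_perm must be at least 99")
    sp_i, sp_j = pair
    mat = counts_matrix(ds)
    for sp in pair:
        if sp not in mat.columns or mat[sp].sum() == 0:
            raise DegenerateDataError(f"species {sp!r} has zero total catch")
    ci = mat[sp_i].to_numpy()
    cj = mat[sp_j].to_numpy()
    npmle_kwargs = npmle_kwargs or {}

    per_axis = _axis_overlaps_from_vectors(ds.sites, axes, ci, cj, npmle_kwargs)
    observed = unified_overlap(per_axis)

    rng = np.random.default_rng(seed)
    n_sites = len(ci)
    n_i = int(ci.sum())
    # site index of every individual fish of the two species pooled
    fish_sites = np.repeat(np.arange(n_sites), ci + cj)

    null_unified = np.empty(n_perm)
    null_axis = {ax.name: np.empty(n_perm) for ax in axes}
    for b in range(n_perm):
        if unit == "individual":
            perm = rng.permutation(fish_sites)
            pi = np.bincount(perm[:n_i], minlength=n_sites)
            pj = np.bincount(perm[n_i:], minlength=n_sites)
        elif unit == "site":
            swap = rng.random(n_sites) < 0.5
            pi = np.where(swap, cj, ci)
            pj = np.where(swap, ci, cj)
        else:
            raise DomainError(f"unknown permutation unit {unit!r}")
        try:
            pa = _axis_overlaps_from_vectors(ds.sites, axes, pi, pj,
                                             npmle_kwargs)
        except DegenerateDataError:
            # a permutation emptied a species from every site class; treat
            # as maximal separation under H0
            pa = {ax.name: 0.0 for ax in axes}
        for name, v in pa.items():
            null_axis[name][b] = v
        null_unified[b] = unified_overlap(pa)

    p = (1.0 + np.sum(null_unified <= observed)) / (n_perm + 1.0)
    per_axis_p = {
        name: (1.0 + np.sum(null_axis[name] <= per_axis[name])) / (n_perm + 1.0)
        for name in per_axis
    }
    return OverlapResult(
        species_pair=pair, per_axis_no=per_axis, unified_no=observed,
        null_distribution=null_unified, p_value=float(p),
        per_axis_p=per_axis_p, n_perm=n_perm,
    )


def pairwise_overlap(ds: Dataset, axes: list[AxisSpec] | None = None,
                     n_perm: int = 1000, seed: int | None = None,
                     **kwargs) -> list[OverlapResult]:
    """Permutation-tested unified NO for every species pair in the dataset."""
    axes = axes if axes is not None else default_axes()
    species = ds.species()
    rng = np.random.default_rng(seed)
    out = []
    for a in range(len(species)):
        for b in range(a + 1, len(species)):
            out.append(permutation_test(
                ds, axes, (species[a], species[b]), n_perm=n_perm,
                seed=int(rng.integers(2**31 - 1)), **kwargs))
    return out
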