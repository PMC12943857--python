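"""Semivariogram estimation, model fitting, Ordinary Kriging and co-Kriging.

Spatial structure is summarized by isotropic semivariogram models

    gamma(h) = c0 + c * g(h / R)

with nugget ``c0``, partial sill ``c`` and effective range ``R`` (the
distance at which gamma reaches ~95% of the sill). Supported families:

- exponential:  g = 1 - exp(-3 h / R)
- spherical:    g = 1.5 (h/R') - 0.5 (h/R')^3 for h < R', else 1, with R' = R
- gaussian:     g = 1 - exp(-3 (h/R)^2)

Kriging uses a global neighborhood (every sample contributes to every
query), appropriate at the few-hundred-plot scale this package targets; a
``max_neighbors`` option subsets to the nearest samples for larger n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = [
    "VariogramModel",
    "CoregionalizationModel",
    "EmpiricalVariogram",
    "KrigingResult",
    "empirical_semivariogram",
    "cross_semivariogram",
    "fit_variogram",
    "fit_lmc",
    "variogram_value",
    "ordinary_kriging",
    "co_kriging",
    "loo_diagnostics",
]

_FAMILIES = ("exponential", "spherical", "gaussian")


@dataclass(frozen=True)
class VariogramModel:
    """Isotropic semivariogram model with an effective-range convention."""

    family: str
    nugget: float
    partial_sill: float
    effective_range: float

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial sill must be non-negative")
        if not self.effective_range > 0:
            raise ValueError("effective range must be positive")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    @property
    def nugget_sill_ratio(self) -> float:
        s = self.sill
        return self.nugget / s if s > 0 else 1.0

    def __call__(self, h) -> np.ndarray:
        return variogram_value(self, h)

    def covariance(self, h) -> np.ndarray:
        """Covariance function C(h) = sill - gamma(h) of the implied field."""
        h = np.asarray(h, dtype=float)
        return self.sill - variogram_value(self, h)


def _structure(family: str, h: np.ndarray, rng: float) -> np.ndarray:
    """Unit-sill structural component g(h); g(0)=0, g(inf)=1."""
    if family == "exponential":
        return 1.0 - np.exp(-3.0 * h / rng)
    if family == "gaussian":
        return 1.0 - np.exp(-3.0 * (h / rng) ** 2)
    # spherical: effective range equals the true range
    hr = np.minimum(h / rng, 1.0)
    return 1.5 * hr - 0.5 * hr**3


def variogram_value(model: VariogramModel, h) -> np.ndarray:
    """Evaluate gamma(h); gamma(0) = 0 exactly (the nugget is a limit from above)."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("lag distances must be non-negative")
    g = model.nugget + model.partial_sill * _structure(
        model.family, h, model.effective_range
    )
    return np.where(h > 0, g, 0.0)


@dataclass(frozen=True)
class CoregionalizationModel:
    """Linear model of coregionalization for (primary, secondary).

    Direct and cross variograms share the family and effective range per
    structure (one nugget structure + one ranged structure). Positive
    semidefiniteness requires |c12| <= sqrt(c1*c2) for both structures.
    """

    family: str
    effective_range: float
    nugget_1: float
    nugget_2: float
    nugget_12: float
    sill_1: float
    sill_2: float
    sill_12: float

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if min(self.nugget_1, self.nugget_2, self.sill_1, self.sill_2) < 0:
            raise ValueError("direct-structure coefficients must be non-negative")
        tol = 1e-9
        if abs(self.nugget_12) > np.sqrt(self.nugget_1 * self.nugget_2) + tol:
            raise ValueError("cross nugget violates positive semidefiniteness")
        if abs(self.sill_12) > np.sqrt(self.sill_1 * self.sill_2) + tol:
            raise ValueError("cross partial sill violates positive semidefiniteness")

    def gamma(self, which: str, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        c0, c = {
            "11": (self.nugget_1, self.sill_1),
            "22": (self.nugget_2, self.sill_2),
            "12": (self.nugget_12, self.sill_12),
        }[which]
        g = c0 + c * _structure(self.family, h, self.effective_range)
        return np.where(h > 0, g, 0.0)

    @property
    def primary(self) -> VariogramModel:
        """Direct variogram of the primary variable (the Table-9-style summary)."""
        return VariogramModel(self.family, self.nugget_1, self.sill_1, self.effective_range)


@dataclass
class EmpiricalVariogram:
    """Binned Matheron (or cross) semivariogram estimate."""

    lag_centers: np.ndarray
    gamma_hat: np.ndarray  # NaN where a bin has no pairs
    pair_counts: np.ndarray
    max_dist: float

    def valid(self):
        m = self.pair_counts > 0
        return self.lag_centers[m], self.gamma_hat[m], self.pair_counts[m]


def _bin_pairs(points: np.ndarray, n_lags: int, max_dist: float):
    d = pdist(np.asarray(points, dtype=float))
    edges = np.linspace(0.0, max_dist, n_lags + 1)
    idx = np.digitize(d, edges) - 1
    keep = (idx >= 0) & (idx < n_lags) & (d > 0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return d, idx, keep, centers


def empirical_semivariogram(points, values, n_lags: int = 12, max_dist: float | None = None) -> EmpiricalVariogram:
    """Matheron estimator over equal-width lag bins up to ``max_dist``.

    gamma_hat(h) = sum_{pairs in bin} (z_i - z_j)^2 / (2 N(h)).
    Bins with zero pairs are NaN, not zero. Default ``max_dist`` is half the
    maximum pairwise distance.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(points) < 2:
        raise ValueError("need at least two points")
    if max_dist is None:
        max_dist = 0.5 * float(pdist(points).max())
    if not max_dist > 0:
        raise ValueError("max_dist must be positive")
    _, idx, keep, centers = _bin_pairs(points, n_lags, max_dist)
    dz2 = (pdist(values[:, None], metric="sqeuclidean"))
    counts = np.bincount(idx[keep], minlength=n_lags).astype(int)
    sums = np.bincount(idx[keep], weights=dz2[keep], minlength=n_lags)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / (2.0 * counts), np.nan)
    return EmpiricalVariogram(centers, gamma, counts, float(max_dist))


def cross_semivariogram(points, values1, values2, n_lags: int = 12, max_dist: float | None = None) -> EmpiricalVariogram:
    """Cross semivariogram of two collocated variables.

    gamma12_hat(h) = sum (z1_i - z1_j)(z2_i - z2_j) / (2 N(h)).
    """
    points = np.asarray(points, dtype=float)
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    if len(points) < 2:
        raise ValueError("need at least two points")
    if v1.shape != v2.shape or len(v1) != len(points):
        raise ValueError("variables must be collocated with the points")
    if max_dist is None:
        max_dist = 0.5 * float(pdist(points).max())
    _, idx, keep, centers = _bin_pairs(points, n_lags, max_dist)
    i, j = np.triu_indices(len(points), k=1)
    prod = (v1[i] - v1[j]) * (v2[i] - v2[j])
    counts = np.bincount(idx[keep], minlength=n_lags).astype(int)
    sums = np.bincount(idx[keep], weights=prod[keep], minlength=n_lags)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / (2.0 * counts), np.nan)
    return EmpiricalVariogram(centers, gamma, counts, float(max_dist))


def fit_variogram(emp: EmpiricalVariogram, family: str = "exponential", weights: str = "cressie") -> VariogramModel:
    """Weighted least-squares fit of a variogram model to binned estimates.

    Default weighting is Cressie's N(h)/gamma_model(h)^2, recomputed at each
    iteration; ``weights='npairs'`` uses plain N(h). A flat empirical
    variogram degenerates gracefully to a pure-nugget model.
    """
    h, g, n = emp.valid()
    if len(h) < 3:
        raise ValueError("need at least three non-empty lag bins")
    if weights not in ("cressie", "npairs"):
        raise ValueError("weights must be 'cressie' or 'npairs'")

    sill0 = float(np.nanmean(g[-max(1, len(g) // 3):]))
    sill0 = max(sill0, 1e-12)
    nug0 = float(np.clip(g[0], 0.0, sill0))
    rng0 = float(h[len(h) // 2])

    def resid(theta):
        c0, c, r = theta
        model_g = c0 + c * _structure(family, h, r)
        if weights == "cressie":
            w = np.sqrt(n) / np.maximum(model_g, 1e-12)
        else:
            w = np.sqrt(n)
        return w * (model_g - g)

    # the range is unidentifiable beyond the sampled lags (an exponential with
    # R >> max(h) is indistinguishable from a line), so it is capped at twice
    # the largest lag center
    r_max = 2.0 * h[-1]
    best = None
    for r_init in (rng0, 0.9 * r_max, h[0] + 0.25 * (h[-1] - h[0])):
        sol = least_squares(
            resid,
            x0=[nug0, max(sill0 - nug0, 1e-6), min(max(r_init, 1e-6), r_max)],
            bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, r_max]),
            max_nfev=2000,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    c0, c, r = best.x
    if c < max(1e-10, 1e-6 * c0):
        # degenerate flat variogram: pure nugget
        return VariogramModel(family, float(max(c0, np.average(g, weights=n))), 0.0, float(h[-1]))
    # a structure exhausted before the first observed lag is unidentifiable
    # from (and riskier than) a nugget: without closer pairs the two models
    # agree at every sampled distance, so prefer the nugget interpretation
    if _structure(family, h[0], r) > 0.95:
        return VariogramModel(family, float(c0 + c), 0.0, float(h[-1]))
    return VariogramModel(family, float(c0), float(c), float(r))


def fit_lmc(points, primary, secondary, family: str = "exponential", n_lags: int = 12, max_dist: float | None = None) -> CoregionalizationModel:
    """Fit a two-structure LMC to collocated primary/secondary observations.

    The primary direct variogram is fitted first and fixes the shared
    effective range; secondary and cross structures are then fitted with the
    range held, and the cross coefficients are clipped into the positive
    semidefinite cone |c12| <= sqrt(c1 c2).
    """
    points = np.asarray(points, dtype=float)
    emp1 = empirical_semivariogram(points, primary, n_lags, max_dist)
    m1 = fit_variogram(emp1, family)
    rng = m1.effective_range

    def fit_fixed_range(emp, signed=False):
        h, g, n = emp.valid()

        def resid(theta):
            c0, c = theta
            model_g = c0 + c * _structure(family, h, rng)
            w = np.sqrt(n) / np.maximum(np.abs(model_g), 1e-12)
            return w * (model_g - g)

        lo = [-np.inf, -np.inf] if signed else [0.0, 0.0]
        x0 = [float(g[0]), float(np.mean(g[-3:]) - g[0])]
        if not signed:
            x0 = [max(x0[0], 0.0), max(x0[1], 1e-6)]
        sol = least_squares(resid, x0=x0, bounds=(lo, [np.inf, np.inf]), max_nfev=2000)
        return float(sol.x[0]), float(sol.x[1])

    emp2 = empirical_semivariogram(points, secondary, n_lags, max_dist)
    c0_2, c_2 = fit_fixed_range(emp2)
    emp12 = cross_semivariogram(points, primary, secondary, n_lags, max_dist)
    c0_12, c_12 = fit_fixed_range(emp12, signed=True)

    # project onto the PSD cone, structure by structure
    lim0 = np.sqrt(m1.nugget * c0_2)
    lim1 = np.sqrt(m1.partial_sill * c_2)
    c0_12 = float(np.clip(c0_12, -lim0, lim0))
    c_12 = float(np.clip(c_12, -lim1, lim1))
    return CoregionalizationModel(
        family, rng, m1.nugget, c0_2, c0_12, m1.partial_sill, c_2, c_12
    )


@dataclass
class KrigingResult:
    predictions: np.ndarray
    variance: np.ndarray
    weights: np.ndarray | None = None  # (n_query, n_sample[, 2]) if requested


def _dedup(points: np.ndarray, *value_arrays):
    """Average values at duplicate coordinates (exact duplicates only)."""
    uniq, inv = np.unique(points, axis=0, return_inverse=True)
    if len(uniq) == len(points):
        return (points,) + value_arrays
    outs = []
    for v in value_arrays:
        sums = np.bincount(inv, weights=v, minlength=len(uniq))
        cnts = np.bincount(inv, minlength=len(uniq))
        outs.append(sums / cnts)
    warnings.warn(f"averaged {len(points) - len(uniq)} duplicate sample location(s)")
    return (uniq,) + tuple(outs)


def ordinary_kriging(model: VariogramModel, sample_points, sample_values, query_points,
                     return_weights: bool = False, max_neighbors: int | None = None) -> KrigingResult:
    """Ordinary Kriging with the unbiasedness constraint (weights sum to 1).

    Solves per query the standard system in semivariance form with a Lagrange
    multiplier; prediction = sum(lambda_i z_i), variance
    = sum(lambda_i gamma(h_i0)) + mu. Duplicate sample coordinates are
    averaged before solving.
    """
    sp = np.atleast_2d(np.asarray(sample_points, dtype=float))
    sv = np.asarray(sample_values, dtype=float)
    qp = np.atleast_2d(np.asarray(query_points, dtype=float))
    if len(sp) < 2:
        raise ValueError("need at least two samples")
    sp, sv = _dedup(sp, sv)
    n = len(sp)

    if max_neighbors is not None and max_neighbors < n:
        tree = cKDTree(sp)
        _, nbr = tree.query(qp, k=max_neighbors)
        preds = np.empty(len(qp))
        var = np.empty(len(qp))
        for q in range(len(qp)):
            sub = nbr[q]
            r = ordinary_kriging(model, sp[sub], sv[sub], qp[q : q + 1])
            preds[q] = r.predictions[0]
            var[q] = r.variance[0]
        return KrigingResult(preds, var)

    gamma_ss = variogram_value(model, squareform(pdist(sp)))
    a = np.zeros((n + 1, n + 1))
    a[:n, :n] = gamma_ss
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    b = np.empty((n + 1, len(qp)))
    b[:n] = variogram_value(model, cdist(sp, qp))
    b[n] = 1.0
    try:
        lam = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular OK system (n={n}, model={model})"
        ) from exc
    w = lam[:n]
    mu = lam[n]
    preds = w.T @ sv
    var = np.maximum(np.einsum("iq,iq->q", w, b[:n]) + mu, 0.0)
    return KrigingResult(preds, var, w.T if return_weights else None)


def co_kriging(lmc: CoregionalizationModel, primary_points, primary_values,
               secondary_points, secondary_values, query_points,
               return_weights: bool = False) -> KrigingResult:
    """Traditional (unbiased) co-Kriging with one secondary variable.

    Primary weights sum to 1, secondary weights sum to 0. The secondary may
    be observed at a different (e.g. denser) point set than the primary.
    """
    p1 = np.atleast_2d(np.asarray(primary_points, dtype=float))
    z1 = np.asarray(primary_values, dtype=float)
    p2 = np.atleast_2d(np.asarray(secondary_points, dtype=float))
    z2 = np.asarray(secondary_values, dtype=float)
    qp = np.atleast_2d(np.asarray(query_points, dtype=float))
    p1, z1 = _dedup(p1, z1)
    p2, z2 = _dedup(p2, z2)
    n1, n2 = len(p1), len(p2)

    a = np.zeros((n1 + n2 + 2, n1 + n2 + 2))
    a[:n1, :n1] = lmc.gamma("11", squareform(pdist(p1)))
    a[n1 : n1 + n2, n1 : n1 + n2] = lmc.gamma("22", squareform(pdist(p2)))
    g12 = lmc.gamma("12", cdist(p1, p2))
    a[:n1, n1 : n1 + n2] = g12
    a[n1 : n1 + n2, :n1] = g12.T
    a[:n1, n1 + n2] = 1.0
    a[n1 + n2, :n1] = 1.0
    a[n1 : n1 + n2, n1 + n2 + 1] = 1.0
    a[n1 + n2 + 1, n1 : n1 + n2] = 1.0

    b = np.zeros((n1 + n2 + 2, len(qp)))
    b[:n1] = lmc.gamma("11", cdist(p1, qp))
    b[n1 : n1 + n2] = lmc.gamma("12", cdist(p2, qp))
    b[n1 + n2] = 1.0
    # a perfectly redundant secondary (e.g. a copy of the primary) makes the
    # system singular while the prediction stays well defined; fall back to
    # the minimum-norm solution in that case
    try:
        lam = np.linalg.solve(a, b)
        if not np.all(np.isfinite(lam)) or np.abs(a @ lam - b).max() > 1e-6 * max(
            1.0, np.abs(b).max()
        ):
            raise np.linalg.LinAlgError("ill-conditioned CK system")
    except np.linalg.LinAlgError:
        warnings.warn(f"singular CK system (n1={n1}, n2={n2}); using the minimum-norm solution")
        lam = np.linalg.lstsq(a, b, rcond=None)[0]
    w1 = lam[:n1]
    w2 = lam[n1 : n1 + n2]
    mu1 = lam[n1 + n2]
    preds = w1.T @ z1 + w2.T @ z2
    var = np.maximum(
        np.einsum("iq,iq->q", w1, b[:n1])
        + np.einsum("iq,iq->q", w2, b[n1 : n1 + n2])
        + mu1,
        0.0,
    )
    weights = None
    if return_weights:
        weights = np.stack([w1.T, np.pad(w2.T, ((0, 0), (0, 0)))], axis=-1) if n1 == n2 else (w1.T, w2.T)
    return KrigingResult(preds, var, weights)


def loo_diagnostics(model, sample_points, sample_values,
                    secondary_points=None, secondary_values=None) -> tuple[float, float]:
    """Leave-one-out kriging diagnostics (RMS, RMSS).

    RMS = sqrt(mean(eps^2)) with eps = observed - LOO prediction; RMSS is the
    same with eps standardized by the kriging standard error at the held-out
    point. Points where the kriging variance is zero are excluded from RMSS
    with a warning. Pass a :class:`CoregionalizationModel` together with the
    secondary observations to diagnose co-Kriging.
    """
    sp = np.atleast_2d(np.asarray(sample_points, dtype=float))
    sv = np.asarray(sample_values, dtype=float)
    n = len(sp)
    if n < 3:
        raise ValueError("need at least three samples")
    eps = np.empty(n)
    sk = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        if isinstance(model, CoregionalizationModel):
            r = co_kriging(model, sp[keep], sv[keep], secondary_points, secondary_values, sp[i : i + 1])
        else:
            r = ordinary_kriging(model, sp[keep], sv[keep], sp[i : i + 1])
        eps[i] = sv[i] - r.predictions[0]
        sk[i] = np.sqrt(r.variance[0])
    rms = float(np.sqrt(np.mean(eps**2)))
    ok = sk > 0
    if not ok.all():
        warnings.warn(f"excluded {np.sum(~ok)} point(s) with zero kriging variance from RMSS")
    rmss = float(np.sqrt(np.mean((eps[ok] / sk[ok]) ** 2))) if ok.any() else float("nan")
    return rms, rmss
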