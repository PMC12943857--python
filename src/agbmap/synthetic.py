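"""Synthetic forest landscape generator.

Real national-forest-inventory plot data of the kind this pipeline targets
are confidential, so the package ships a generator that reproduces the
statistical structure the downstream stages rely on:

- aboveground biomass (AGB) restricted to a configurable range
  (default 36.68-184.84 t/ha, the regime of subtropical plantation/secondary
  forest plots), with mean ~102 and sd ~22 t/ha;
- systematic plot sampling on a regular grid with optional jitter;
- saturating (logistic) optical reflectance and SAR backscatter responses to
  AGB, so that spectral sensitivity flattens at high biomass;
- plot-scale AGB variability invisible to the covariates (the mismatch
  between the ~0.08 ha plot support and the 10 m pixel, plus allometric and
  measurement error), which bounds attainable validation R^2 near the levels
  reported for real plot data (~0.6-0.7) and dominates the nugget of the
  residual variogram;
- a spatially autocorrelated residual field, also invisible to the
  covariates, so that a purely covariate-driven regressor leaves
  exponential-variogram residuals with a high nugget/sill ratio (~0.85-0.9)
  and a correlation range of a few plot spacings.

Every operation is a pure function of (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .geostat import VariogramModel
from .grids import GridGeometry, RasterStack

__all__ = [
    "BandResponse",
    "ScenarioConfig",
    "LandscapeScenario",
    "simulate_grf",
    "simulate_grf_points",
    "sample_plots",
    "build_scenario",
]

OPTICAL_BANDS = ("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12")


def simulate_grf(grid: GridGeometry, model: VariogramModel, seed: int) -> np.ndarray:
    """Zero-mean Gaussian random field on a grid via circulant embedding.

    The field's covariance is C(h) = sill - gamma(h) for the given variogram
    model. The ranged component is simulated spectrally on a doubled torus
    (exact for embeddings whose circulant eigenvalues are non-negative; tiny
    negative eigenvalues from numerical round-off are clipped, larger ones
    abort); the nugget component is added as i.i.d. noise.
    """
    rng = np.random.default_rng(seed)
    nr, nc = grid.n_rows, grid.n_cols
    out = np.zeros((nr, nc))
    if model.partial_sill > 0:
        m, n = 2 * nr, 2 * nc
        # torus distances on the doubled grid
        dr = np.minimum(np.arange(m), m - np.arange(m)) * grid.cell_size
        dc = np.minimum(np.arange(n), n - np.arange(n)) * grid.cell_size
        h = np.sqrt(dr[:, None] ** 2 + dc[None, :] ** 2)
        structured = VariogramModel(model.family, 0.0, model.partial_sill, model.effective_range)
        cov = structured.covariance(h)
        lam = np.fft.fft2(cov).real
        if lam.min() < -1e-8 * max(lam.max(), 1.0):
            raise ValueError(
                f"circulant embedding not positive semidefinite for {model} "
                f"(min eigenvalue {lam.min():.3g}); enlarge the grid or reduce the range"
            )
        lam = np.maximum(lam, 0.0)
        eps = rng.standard_normal((m, n)) + 1j * rng.standard_normal((m, n))
        f = np.fft.fft2(eps * np.sqrt(lam / (m * n)))
        out += f.real[:nr, :nc] / np.sqrt(2.0) + f.imag[:nr, :nc] / np.sqrt(2.0)
    if model.nugget > 0:
        out += np.sqrt(model.nugget) * rng.standard_normal((nr, nc))
    return out


def simulate_grf_points(points, model: VariogramModel, seed: int, max_points: int = 3000) -> np.ndarray:
    """Zero-mean GRF at arbitrary coordinates via dense Cholesky (n <= 3000)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(points)
    if n > max_points:
        raise ValueError(f"dense simulation limited to {max_points} points, got {n}")
    rng = np.random.default_rng(seed)
    from scipy.spatial.distance import pdist, squareform

    h = squareform(pdist(points))
    cov = model.covariance(h)
    np.fill_diagonal(cov, model.sill)
    # jitter for numerical PD when the nugget is zero
    chol = np.linalg.cholesky(cov + 1e-10 * model.sill * np.eye(n))
    return chol @ rng.standard_normal(n)


def sample_plots(grid: GridGeometry, spacing_x: float, spacing_y: float,
                 jitter: float, seed: int, agb_truth: np.ndarray) -> pd.DataFrame:
    """Systematic plot sample on a regular coordinate grid.

    Plot locations sit at regular intersections offset by half a spacing from
    the raster edge, displaced by uniform jitter in [-jitter, +jitter] per
    axis, and clipped to the raster extent. Each plot's AGB is read from the
    cell containing its (jittered) center.
    """
    if spacing_x <= grid.cell_size or spacing_y <= grid.cell_size:
        raise ValueError("plot spacing must exceed the cell size")
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    rng = np.random.default_rng(seed)
    xs = np.arange(grid.origin_x + spacing_x / 2, grid.origin_x + grid.width, spacing_x)
    ys = np.arange(grid.origin_y - spacing_y / 2, grid.origin_y - grid.height, -spacing_y)
    if len(xs) == 0 or len(ys) == 0:
        warnings.warn("plot spacing exceeds the raster extent; zero plots sampled")
        return pd.DataFrame(columns=["plot_id", "x", "y", "agb_t_ha"])
    gx, gy = np.meshgrid(xs, ys)
    x = gx.ravel()
    y = gy.ravel()
    if jitter > 0:
        x = x + rng.uniform(-jitter, jitter, size=x.shape)
        y = y + rng.uniform(-jitter, jitter, size=y.shape)
    inside = grid.contains(x, y)
    x, y = x[inside], y[inside]
    r, c = grid.cell_index(x, y)
    return pd.DataFrame(
        {
            "plot_id": np.arange(1, len(x) + 1),
            "x": x,
            "y": y,
            "agb_t_ha": np.asarray(agb_truth)[r, c],
        }
    )


@dataclass(frozen=True)
class BandResponse:
    """4-parameter logistic reflectance/backscatter response to AGB.

    value(a) = low + (high - low) / (1 + exp(-(a - midpoint) / scale))

    ``high < low`` yields a monotone decreasing response (visible/SWIR).
    """

    low: float
    high: float
    midpoint: float
    scale: float

    def __call__(self, agb) -> np.ndarray:
        a = np.asarray(agb, dtype=float)
        return self.low + (self.high - self.low) / (1.0 + np.exp(-(a - self.midpoint) / self.scale))


def _default_optical(saturation_agb: float, logistic_scale: float) -> dict[str, BandResponse]:
    mid = saturation_agb - 2.0 * logistic_scale
    s = logistic_scale
    amp = {
        # (low, high): visible reflectance falls with biomass, NIR rises,
        # SWIR falls (leaf water absorption)
        "B2": (0.060, 0.020), "B3": (0.080, 0.040), "B4": (0.090, 0.030),
        "B5": (0.100, 0.180), "B6": (0.120, 0.280), "B7": (0.140, 0.330),
        "B8": (0.150, 0.450), "B8A": (0.160, 0.460),
        "B11": (0.250, 0.120), "B12": (0.200, 0.080),
    }
    return {b: BandResponse(lo, hi, mid, s) for b, (lo, hi) in amp.items()}


@dataclass(frozen=True)
class ScenarioConfig:
    """All knobs of the synthetic landscape; defaults define the study conditions.

    The default grid is 128 x 128 cells of 100 m (12.8 km x 12.8 km): a
    scaled-down study region that preserves the real-data ratios of plot
    spacing to domain size and of residual correlation range to plot spacing
    (range ~ 5 plot spacings ~ 0.27 of the domain). Plot spacing 640 m gives a
    systematic 20 x 20 sample (400 plots), the desk-scale analogue of ~400
    inventory plots.
    """

    n_rows: int = 128
    n_cols: int = 128
    cell_size: float = 100.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    # AGB truth
    agb_min: float = 36.68
    agb_max: float = 184.84
    agb_mean: float = 101.92
    elev_effect: float = 12.0      # t/ha per sd of elevation
    agb_grf_sd: float = 18.0       # t/ha, smooth biomass heterogeneity
    agb_grf_range_frac: float = 0.3  # of the domain diagonal-free width
    micro_sd: float = 11.5         # t/ha i.i.d. plot-scale AGB variability
    #                                (support mismatch + allometric error),
    #                                part of the truth but not of the signal
    #                                the covariates respond to
    # terrain
    elev_min: float = 50.0
    elev_max: float = 1500.0
    elev_range_frac: float = 0.5
    elev_smooth_sigma: float = 3.0  # cells of Gaussian smoothing
    elev_response_shift: float = 18.0  # t/ha per sd of elevation
    #   forest composition changes along the altitudinal gradient, shifting
    #   every spectral response curve: the same reflectance corresponds to a
    #   different AGB at a different elevation, so inverting the signal
    #   requires conditioning on elevation (a smooth interaction)
    # optical response
    saturation_agb: float = 160.0  # AGB above which optical response is flat
    logistic_scale: float = 35.0   # t/ha
    spectral_noise_sd: float = 4.0  # t/ha, shared across optical bands
    band_noise_frac: float = 0.10  # per-band artifact amplitude, fraction of band range
    band_noise_range: float = 500.0  # metres; patch scale of per-band artifacts
    #   per-band noise is a spatially correlated field (sensor calibration,
    #   BRDF and atmospheric artifacts are patchy, not white): local texture
    #   windows cannot average it away, only combining many bands can
    # SAR response (linear power)
    sar_noise_sd: float = 14.0     # t/ha, shared across polarizations
    speckle_sd: float = 0.10       # lognormal sd of multiplicative speckle
    # injected residual spatial structure (invisible to the covariates)
    residual_family: str = "exponential"
    residual_nugget: float = 0.0
    residual_partial_sill: float = 20.0  # (t/ha)^2
    residual_range: float = 3400.0       # metres
    # plot sampling
    spacing_x: float = 640.0
    spacing_y: float = 640.0
    jitter: float = 50.0

    def __post_init__(self) -> None:
        if self.saturation_agb <= self.agb_min:
            raise ValueError("optical saturation point must exceed the AGB minimum")
        for name in ("spectral_noise_sd", "band_noise_frac", "sar_noise_sd",
                     "speckle_sd", "micro_sd", "residual_nugget", "residual_partial_sill"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.agb_min < self.agb_max:
            raise ValueError("agb_min must be below agb_max")

    @property
    def grid(self) -> GridGeometry:
        return GridGeometry(self.n_rows, self.n_cols, self.cell_size,
                            self.origin_x, self.origin_y)

    @property
    def residual_model(self) -> VariogramModel:
        return VariogramModel(self.residual_family, self.residual_nugget,
                              self.residual_partial_sill, self.residual_range)

    @property
    def optical_responses(self) -> dict[str, BandResponse]:
        return _default_optical(self.saturation_agb, self.logistic_scale)

    @property
    def sar_responses(self) -> dict[str, BandResponse]:
        # HV (cross-pol, volume scattering) responds more steeply than HH
        return {
            "HH": BandResponse(0.020, 0.080, 110.0, 45.0),
            "HV": BandResponse(0.004, 0.054, 95.0, 30.0),
        }

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LandscapeScenario:
    """A complete synthetic study: covariates, truth, plots and provenance."""

    grid: GridGeometry
    stack: RasterStack
    agb_truth: np.ndarray
    agb_base: np.ndarray  # covariate-visible component (truth minus injected residual)
    plots: pd.DataFrame
    residual_model: VariogramModel
    seed: int
    config: ScenarioConfig = field(repr=False, default=None)


def build_scenario(config: ScenarioConfig | None = None, seed: int = 0) -> LandscapeScenario:
    """Generate a full landscape scenario; pure function of (config, seed)."""
    cfg = config or ScenarioConfig()
    grid = cfg.grid
    domain = min(grid.width, grid.height)
    children = np.random.SeedSequence(seed).spawn(8)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in children]
    rng = np.random.default_rng(sub[0])

    # --- terrain: smooth GRF rescaled to the configured elevation range
    dem_model = VariogramModel("exponential", 0.0, 1.0, cfg.elev_range_frac * domain)
    dem_raw = simulate_grf(grid, dem_model, sub[1])
    if cfg.elev_smooth_sigma > 0:
        dem_raw = ndimage.gaussian_filter(dem_raw, cfg.elev_smooth_sigma)
    lo, hi = dem_raw.min(), dem_raw.max()
    span = hi - lo if hi > lo else 1.0
    dem = cfg.elev_min + (dem_raw - lo) / span * (cfg.elev_max - cfg.elev_min)
    dem_z = (dem - dem.mean()) / (dem.std() if dem.std() > 0 else 1.0)

    # --- covariate-visible AGB component
    agb_grf_model = VariogramModel("exponential", 0.0, cfg.agb_grf_sd**2,
                                   cfg.agb_grf_range_frac * domain)
    agb_grf = simulate_grf(grid, agb_grf_model, sub[2])
    agb_base = np.clip(cfg.agb_mean + cfg.elev_effect * dem_z + agb_grf,
                       cfg.agb_min, cfg.agb_max)

    # --- residual components invisible to the covariates: a structured GRF
    # (regional drivers the covariates miss) plus i.i.d. plot-scale
    # variability (support mismatch, allometric and measurement error)
    if cfg.residual_model.sill > 0:
        resid_field = simulate_grf(grid, cfg.residual_model, sub[3])
    else:
        resid_field = np.zeros(grid.shape)
    micro = cfg.micro_sd * rng.standard_normal(grid.shape)
    agb_truth = np.clip(agb_base + resid_field + micro, cfg.agb_min, cfg.agb_max)

    # --- optical bands: logistic responses to a commonly-perturbed AGB signal
    stack = RasterStack(grid)
    common_opt = cfg.spectral_noise_sd * rng.standard_normal(grid.shape)
    agb_opt = agb_base + common_opt - cfg.elev_response_shift * dem_z
    band_noise_model = VariogramModel("exponential", 0.0, 1.0, cfg.band_noise_range)
    for bi, (name, resp) in enumerate(cfg.optical_responses.items()):
        band = resp(agb_opt)
        amp = abs(resp.high - resp.low)
        if cfg.band_noise_frac > 0:
            artifact = simulate_grf(grid, band_noise_model, sub[5] + bi)
            band = band + cfg.band_noise_frac * amp * artifact
        stack.add(name, np.clip(band, 0.0, 1.0))

    # --- SAR backscatter in linear power with multiplicative speckle
    common_sar = cfg.sar_noise_sd * rng.standard_normal(grid.shape)
    agb_sar = agb_base + common_sar - 0.5 * cfg.elev_response_shift * dem_z
    for name, resp in cfg.sar_responses.items():
        band = resp(agb_sar)
        if cfg.speckle_sd > 0:
            band = band * np.exp(cfg.speckle_sd * rng.standard_normal(grid.shape)
                                 - 0.5 * cfg.speckle_sd**2)
        stack.add(name, band)

    stack.add("DEM", dem)

    plots = sample_plots(grid, cfg.spacing_x, cfg.spacing_y, cfg.jitter, sub[4], agb_truth)
    return LandscapeScenario(grid, stack, agb_truth, agb_base, plots,
                             cfg.residual_model, seed, cfg)
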