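"""Predictor construction: spectral indices, PCA, GLCM textures, terrain.

The candidate universe has exactly 50 variables: the 10 optical reflectance
bands, 5 vegetation indices, the first 3 principal components of the optical
bands, 24 GLCM textures of PC1 (8 metrics x window sizes 3/5/7), 5 SAR
polarization features and 3 terrain variables.

All derived bands propagate nodata (NaN) from their inputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .grids import GridGeometry, RasterStack

__all__ = [
    "GlcmConfig",
    "vegetation_indices",
    "sar_indices",
    "pca",
    "glcm_textures",
    "glcm_textures_multi",
    "terrain",
    "resample",
    "extract_features",
    "assemble_feature_stack",
    "palsar_dn_to_linear",
    "GLCM_METRICS",
    "FEATURE_ORDER",
]

log = logging.getLogger(__name__)

GLCM_METRICS = (
    "mean", "variance", "homogeneity", "contrast",
    "dissimilarity", "entropy", "secondmoment", "correlation",
)
GLCM_WINDOWS = (3, 5, 7)

OPTICAL = ("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12")
VI_NAMES = ("NDVI", "RVI", "ARVI", "EVI", "mNDVI")
SAR_NAMES = ("HH", "HV", "HH/HV", "RFDI", "RVI_radar")
TERRAIN_NAMES = ("elevation", "slope", "aspect")
FEATURE_ORDER = (
    list(OPTICAL)
    + list(VI_NAMES)
    + ["PC1", "PC2", "PC3"]
    + [f"{m}{w}{w}" for w in GLCM_WINDOWS for m in GLCM_METRICS]
    + list(SAR_NAMES)
    + list(TERRAIN_NAMES)
)


def _safe_div(num, den):
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    out = np.where(np.isfinite(out), out, np.nan)
    return out


def vegetation_indices(stack: RasterStack) -> RasterStack:
    """NDVI, RVI, ARVI, EVI and mNDVI from the RED/NIR/BLUE bands.

    NIR = B8, RED = B4, BLUE = B2, reflectance in [0, 1]. Cells where a
    denominator vanishes become nodata.
    """
    stack.require("B2", "B4", "B8")
    nir, red, blue = stack["B8"], stack["B4"], stack["B2"]
    out = RasterStack(stack.grid)
    out.add("NDVI", _safe_div(nir - red, nir + red))
    out.add("RVI", _safe_div(nir, red))
    out.add("ARVI", _safe_div(nir - (2 * red - blue), nir + (2 * red - blue)))
    out.add("EVI", _safe_div(2.5 * (nir - red), nir + 6 * red - 7.5 * blue + 1))
    out.add("mNDVI", _safe_div(nir - red, nir + red - 2 * blue))
    return out


def sar_indices(stack: RasterStack) -> RasterStack:
    """HH, HV (linear power), HH/HV ratio, RFDI and radar RVI.

    RFDI = (HH - HV)/(HH + HV); radar RVI = sqrt(HH/(HH + HV)) * (HH/HV).
    Non-positive backscatter cells become nodata (logged).
    """
    stack.require("HH", "HV")
    hh = stack["HH"].copy()
    hv = stack["HV"].copy()
    bad = ~((hh > 0) & (hv > 0))
    n_bad = int(np.sum(bad & np.isfinite(hh) & np.isfinite(hv)))
    if n_bad:
        log.warning("%d cells with non-positive backscatter set to nodata", n_bad)
    hh[bad] = np.nan
    hv[bad] = np.nan
    out = RasterStack(stack.grid)
    out.add("HH", hh)
    out.add("HV", hv)
    out.add("HH/HV", _safe_div(hh, hv))
    out.add("RFDI", _safe_div(hh - hv, hh + hv))
    out.add("RVI_radar", np.sqrt(_safe_div(hh, hh + hv)) * _safe_div(hh, hv))
    return out


def palsar_dn_to_linear(dn: np.ndarray) -> np.ndarray:
    """Convert PALSAR digital numbers to linear backscatter power.

    gamma0 [dB] = 10 log10(DN^2) - 83, then dB -> linear. Only needed for
    real mosaic products; synthetic scenes are generated in linear power.
    """
    dn = np.asarray(dn, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        db = 10.0 * np.log10(dn**2) - 83.0
    lin = 10.0 ** (db / 10.0)
    return np.where(dn > 0, lin, np.nan)


def pca(stack: RasterStack, band_subset=OPTICAL, n_components: int = 3):
    """Principal components of z-scored bands, in decreasing variance order.

    Returns a stack with bands PC1..PCn plus the explained-variance fractions
    of *all* components (they sum to 1). Loadings are sign-fixed so that each
    component's largest-magnitude loading is positive. Cells with nodata in
    any input band are nodata in every component.
    """
    stack.require(*band_subset)
    mat = np.stack([stack[b] for b in band_subset], axis=-1)
    valid = np.all(np.isfinite(mat), axis=-1)
    x = mat[valid]
    if x.shape[0] <= 1:
        raise ValueError("not enough valid cells for PCA")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    xz = (x - mu) / sd
    full = PCA(n_components=min(len(band_subset), x.shape[0]))
    scores = full.fit_transform(xz)
    rank = np.sum(full.explained_variance_ > 1e-12 * full.explained_variance_[0])
    if rank < n_components:
        warnings.warn(f"rank-deficient input: returning {rank} components instead of {n_components}")
        n_components = int(rank)
    # fix signs: largest-|loading| of each component positive
    comps = full.components_
    for k in range(n_components):
        j = np.argmax(np.abs(comps[k]))
        if comps[k, j] < 0:
            comps[k] = -comps[k]
            scores[:, k] = -scores[:, k]
    out = RasterStack(stack.grid)
    for k in range(n_components):
        band = np.full(stack.grid.shape, np.nan)
        band[valid] = scores[:, k]
        out.add(f"PC{k + 1}", band)
    return out, full.explained_variance_ratio_


@dataclass(frozen=True)
class GlcmConfig:
    """Gray-level co-occurrence configuration.

    ``window`` is the odd moving-window edge; ``levels`` the number of
    equal-width quantization bins; ``offsets`` the displacement vectors whose
    co-occurrence matrices are averaged; ``symmetric`` counts each pair in
    both directions.
    """

    window: int = 7
    levels: int = 32
    offsets: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window must be odd and >= 3")
        if self.levels < 2:
            raise ValueError("need at least two gray levels")
        for off in self.offsets:
            if off == (0, 0):
                raise ValueError("offsets must be nonzero")


def _quantize(band: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width quantization over the finite range; NaN -> -1 sentinel."""
    finite = np.isfinite(band)
    q = np.full(band.shape, -1, dtype=np.int32)
    if not finite.any():
        return q
    lo = band[finite].min()
    hi = band[finite].max()
    if hi == lo:
        q[finite] = 0
        return q
    scaled = (band[finite] - lo) / (hi - lo) * levels
    q[finite] = np.clip(scaled.astype(np.int32), 0, levels - 1)
    return q


def _integral(arr: np.ndarray) -> np.ndarray:
    """Summed-area table with a zero first row/column; float64 accumulator."""
    s = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1) + arr.shape[2:], dtype=np.float64)
    s[1:, 1:] = np.cumsum(np.cumsum(arr, axis=0), axis=1)
    return s


def _pair_integral(code: np.ndarray, valid: np.ndarray, levels: int,
                   offset: tuple[int, int]) -> np.ndarray:
    """Summed-area table of pair indicators for one offset.

    Cell (r, c, a*levels + b) of the underlying indicator is 1 when the pair
    anchored at pixel (r, c) with its partner at (r+dr, c+dc) takes gray
    levels (a, b) and both pixels are valid. The table is window-independent,
    so it is computed once per offset and shared across window sizes.
    """
    h, w = code.shape
    dr, dc = offset
    r0a, r1a = max(0, -dr), h - max(0, dr)
    c0a, c1a = max(0, -dc), w - max(0, dc)
    a = code[r0a:r1a, c0a:c1a]
    b = code[r0a + dr : r1a + dr, c0a + dc : c1a + dc]
    va = valid[r0a:r1a, c0a:c1a] & valid[r0a + dr : r1a + dr, c0a + dc : c1a + dc]
    onehot = np.zeros((h, w, levels * levels), dtype=np.float32)
    rr, cc = np.nonzero(va)
    onehot[rr + r0a, cc + c0a, a[rr, cc] * levels + b[rr, cc]] = 1.0
    return _integral(onehot)


def _counts_from_integral(sat: np.ndarray, shape: tuple[int, int],
                          offset: tuple[int, int], window: int) -> np.ndarray:
    """Windowed co-occurrence counts for one offset and window size.

    For each center pixel, counts the pairs (p, p+offset) with both pixels
    inside the window around the center; windows shrink at raster borders.
    """
    h, w = shape
    dr, dc = offset
    k = window // 2
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    # anchor must satisfy: anchor and anchor+offset both inside the window
    r_lo = np.clip(rows - k + max(0, -dr), 0, h)
    r_hi = np.clip(rows + k - max(0, dr) + 1, 0, h)
    c_lo = np.clip(cols - k + max(0, -dc), 0, w)
    c_hi = np.clip(cols + k - max(0, dc) + 1, 0, w)
    r_hi = np.maximum(r_hi, r_lo)
    c_hi = np.maximum(c_hi, c_lo)
    r_lo_b = np.broadcast_to(r_lo, (h, w))
    r_hi_b = np.broadcast_to(r_hi, (h, w))
    c_lo_b = np.broadcast_to(c_lo, (h, w))
    c_hi_b = np.broadcast_to(c_hi, (h, w))
    return (
        sat[r_hi_b, c_hi_b]
        - sat[r_lo_b, c_hi_b]
        - sat[r_hi_b, c_lo_b]
        + sat[r_lo_b, c_lo_b]
    )


def glcm_textures(band: np.ndarray, config: GlcmConfig, grid: GridGeometry | None = None) -> RasterStack | dict[str, np.ndarray]:
    """Eight GLCM texture statistics in a moving window.

    For every cell, the normalized co-occurrence matrix P is accumulated over
    the configured offsets (and both directions when symmetric) within the
    window centered on the cell; windows shrink at raster borders. The
    statistics are the standard Haralick/Conners forms:

    - mean          sum_i,j i P(i,j)
    - variance      sum_i,j (i - mu_i)^2 P(i,j)
    - homogeneity   sum P / (1 + (i-j)^2)
    - contrast      sum P (i-j)^2
    - dissimilarity sum P |i-j|
    - entropy       -sum P ln P
    - secondmoment  sum P^2
    - correlation   sum (i-mu_i)(j-mu_j) P / (sigma_i sigma_j), 1 where
                    sigma_i sigma_j = 0 (constant window)

    Output band names append the window size, e.g. ``mean77``.
    """
    out_bands = glcm_textures_multi(band, (config.window,), config.levels,
                                    config.offsets, config.symmetric)
    if grid is not None:
        out = RasterStack(grid)
        for k, v in out_bands.items():
            out.add(k, v)
        return out
    return out_bands


def _glcm_stats(counts: np.ndarray, valid: np.ndarray, levels: int) -> dict[str, np.ndarray]:
    """The eight texture statistics from per-pixel co-occurrence counts."""
    h, w = counts.shape[:2]
    total = counts.sum(axis=(2, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / total[..., None, None]

    ii = np.arange(levels, dtype=float)[:, None]
    jj = np.arange(levels, dtype=float)[None, :]
    diff = ii - jj

    pi = p.sum(axis=3)  # marginal over j
    pj = p.sum(axis=2)
    lv = np.arange(levels, dtype=float)
    mu_i = pi @ lv
    mu_j = pj @ lv
    var_i = pi @ (lv**2) - mu_i**2
    var_j = pj @ (lv**2) - mu_j**2
    sig = np.sqrt(np.maximum(var_i, 0.0) * np.maximum(var_j, 0.0))

    mean = np.einsum("hwij,ij->hw", p, np.broadcast_to(ii, (levels, levels)))
    # window-wise sum (i - mu_i)^2 P, expanded as E[i^2] - mu_i^2
    variance = np.einsum("hwij,ij->hw", p, np.broadcast_to(ii**2, (levels, levels))) - mu_i**2
    homogeneity = np.einsum("hwij,ij->hw", p, 1.0 / (1.0 + diff**2))
    contrast = np.einsum("hwij,ij->hw", p, diff**2)
    dissimilarity = np.einsum("hwij,ij->hw", p, np.abs(diff))
    with np.errstate(invalid="ignore", divide="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    entropy = -plogp.sum(axis=(2, 3))
    secondmoment = (p**2).sum(axis=(2, 3))
    cross = np.einsum("hwij,ij->hw", p, ii * jj)
    cov = cross - mu_i * mu_j
    with np.errstate(invalid="ignore", divide="ignore"):
        correlation = np.where(sig > 0, cov / sig, 1.0)

    nod = (total == 0) | ~valid
    results = {
        "mean": mean, "variance": np.maximum(variance, 0.0),
        "homogeneity": homogeneity, "contrast": contrast,
        "dissimilarity": dissimilarity, "entropy": np.maximum(entropy, 0.0),
        "secondmoment": secondmoment, "correlation": correlation,
    }
    for name, arr in results.items():
        arr = arr.astype(float)
        arr[nod] = np.nan
        results[name] = arr
    return results


def glcm_textures_multi(band: np.ndarray, windows=GLCM_WINDOWS, levels: int = 32,
                        offsets=GlcmConfig.__dataclass_fields__["offsets"].default,
                        symmetric: bool = True) -> dict[str, np.ndarray]:
    """Textures for several window sizes, sharing the per-offset pair tables.

    The summed-area table of pair indicators does not depend on the window,
    so it is built once per offset and queried for every window size.
    """
    band = np.asarray(band, dtype=float)
    h, w = band.shape
    if max(windows) > min(h, w):
        raise ValueError("window larger than the raster")
    code = _quantize(band, levels)
    valid = code >= 0
    counts = {win: np.zeros((h, w, levels * levels)) for win in windows}
    for off in offsets:
        sat = _pair_integral(code, valid, levels, off)
        for win in windows:
            counts[win] += _counts_from_integral(sat, (h, w), off, win)
    out: dict[str, np.ndarray] = {}
    for win in windows:
        c = counts[win].reshape(h, w, levels, levels)
        if symmetric:
            c = c + c.transpose(0, 1, 3, 2)
        stats = _glcm_stats(c, valid, levels)
        for name, arr in stats.items():
            out[f"{name}{win}{win}"] = arr
    return out


def terrain(dem: np.ndarray, grid: GridGeometry) -> RasterStack:
    """Elevation, slope (degrees) and aspect (degrees clockwise from north).

    Gradients use Horn's 3x3 finite differences with edge replication. Aspect
    is the direction of steepest *descent*; flat cells get the sentinel -1.
    """
    dem = np.asarray(dem, dtype=float)
    if min(dem.shape) < 2:
        raise ValueError("DEM must be at least 2 x 2")
    pad = np.pad(dem, 1, mode="edge")
    cs = grid.cell_size
    a = pad[:-2, :-2]; b = pad[:-2, 1:-1]; c = pad[:-2, 2:]
    d = pad[1:-1, :-2]; f = pad[1:-1, 2:]
    g = pad[2:, :-2]; hh = pad[2:, 1:-1]; i = pad[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * cs)   # eastward
    dzdy = ((a + 2 * b + c) - (g + 2 * hh + i)) / (8.0 * cs)  # northward
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    flat = (dzdx == 0) & (dzdy == 0)
    aspect[flat] = -1.0
    nod = ~np.isfinite(dem)
    slope[nod] = np.nan
    aspect[nod] = np.nan
    elev = dem.copy()
    out = RasterStack(grid)
    out.add("elevation", elev)
    out.add("slope", slope)
    out.add("aspect", aspect)
    return out


def resample(band: np.ndarray, source_grid: GridGeometry, target_grid: GridGeometry,
             method: str = "bilinear") -> np.ndarray:
    """Interpolate a band at the target grid's cell centers.

    ``nearest`` picks the containing source cell; ``bilinear`` interpolates
    the four surrounding cell centers and is nodata-aware (any NaN corner
    makes the output NaN). Grids must overlap.
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError("method must be 'nearest' or 'bilinear'")
    band = np.asarray(band, dtype=float)
    tx, ty = target_grid.all_centers()
    # extent overlap check
    sx0, sx1 = source_grid.origin_x, source_grid.origin_x + source_grid.width
    sy1, sy0 = source_grid.origin_y, source_grid.origin_y - source_grid.height
    txmin, txmax = tx.min(), tx.max()
    tymin, tymax = ty.min(), ty.max()
    if txmax < sx0 or txmin > sx1 or tymax < sy0 or tymin > sy1:
        raise ValueError("source and target extents are disjoint")
    # fractional index of target centers in source index space
    fc = (tx - source_grid.origin_x) / source_grid.cell_size - 0.5
    fr = (source_grid.origin_y - ty) / source_grid.cell_size - 0.5
    if method == "nearest":
        r = np.clip(np.rint(fr).astype(int), 0, source_grid.n_rows - 1)
        c = np.clip(np.rint(fc).astype(int), 0, source_grid.n_cols - 1)
        out = band[r, c]
        outside = (fr < -0.5) | (fr > source_grid.n_rows - 0.5) | \
                  (fc < -0.5) | (fc > source_grid.n_cols - 0.5)
        out = np.where(outside, np.nan, out)
        return out
    r0 = np.clip(np.floor(fr).astype(int), 0, source_grid.n_rows - 2)
    c0 = np.clip(np.floor(fc).astype(int), 0, source_grid.n_cols - 2)
    wr = np.clip(fr - r0, 0.0, 1.0)
    wc = np.clip(fc - c0, 0.0, 1.0)
    v00 = band[r0, c0]
    v01 = band[r0, c0 + 1]
    v10 = band[r0 + 1, c0]
    v11 = band[r0 + 1, c0 + 1]
    out = (v00 * (1 - wr) * (1 - wc) + v01 * (1 - wr) * wc
           + v10 * wr * (1 - wc) + v11 * wr * wc)
    return out


def extract_features(stack: RasterStack, plots: pd.DataFrame) -> pd.DataFrame:
    """Plot-level feature table: each plot takes the value of its center cell.

    Plots outside the grid or falling on nodata in any band are dropped with
    a logged count. The returned frame is indexed by plot_id, has one column
    per stack band plus the target column ``agb``.
    """
    grid = stack.grid
    inside = grid.contains(plots["x"].to_numpy(), plots["y"].to_numpy())
    n_out = int((~inside).sum())
    if n_out:
        log.warning("dropped %d plot(s) outside the raster extent", n_out)
    kept = plots.loc[np.asarray(inside)]
    r, c = grid.cell_index(kept["x"].to_numpy(), kept["y"].to_numpy())
    data = {name: band[r, c] for name, band in stack.bands.items()}
    table = pd.DataFrame(data, index=pd.Index(kept["plot_id"], name="plot_id"))
    table["agb"] = kept["agb_t_ha"].to_numpy()
    good = table.notna().all(axis=1)
    n_nod = int((~good).sum())
    if n_nod:
        log.warning("dropped %d plot(s) on nodata cells", n_nod)
    table = table.loc[good]
    if len(table) == 0:
        raise ValueError("all plots fell outside the extent or on nodata")
    return table


def assemble_feature_stack(stack: RasterStack, glcm_levels: int = 32,
                           glcm_windows=GLCM_WINDOWS) -> RasterStack:
    """Build the full 50-variable predictor stack from the raw covariates.

    Input must hold the 10 optical bands, HH, HV (linear power) and DEM.
    Textures are computed from PC1 at the given window sizes.
    """
    stack.require(*OPTICAL, "HH", "HV", "DEM")
    out = RasterStack(stack.grid)
    for b in OPTICAL:
        out.add(b, stack[b])
    out.update(vegetation_indices(stack))
    pcs, _ = pca(stack, OPTICAL, 3)
    out.update(pcs)
    for name, arr in glcm_textures_multi(pcs["PC1"], glcm_windows, glcm_levels).items():
        out.add(name, arr)
    out.update(sar_indices(stack))
    out.update(terrain(stack["DEM"], stack.grid))
    return out
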