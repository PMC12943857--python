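"""Ten-fold cross-validation, residual kriging and hybrid map composition.

The hybrid estimator corrects a covariate-driven regression with a
geostatistical model of its own errors:

1. k-fold cross-validation yields an out-of-fold (OOF) prediction for every
   plot; the residual Z(x_i) = C(x_i) - C_hat(x_i) is always computed from a
   model that never saw plot i.
2. The pooled residuals are summarized by an exponential semivariogram
   (Ordinary Kriging) and by a linear model of coregionalization with
   elevation (co-Kriging).
3. Hybrid predictions add the kriged residual surface to the base
   prediction, cell by cell: C_hybrid = C_base + Z_kriged.

Validation metrics follow the standard definitions (R^2, RMSE, MAE, Bias,
CV% = RMSE / mean(observed) * 100), averaged arithmetically across folds,
plus the relative improvement RI = (RMSE_base - RMSE_hybrid) / RMSE_base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geostat
from .features import assemble_feature_stack, extract_features
from .grids import RasterStack
from .selection import fit_rf, importance, select_top_k
from .synthetic import LandscapeScenario
from .transformer import EncoderConfig, TransformerRegressor, build_and_train, train_cv_ensemble

__all__ = [
    "make_folds",
    "compute_residuals",
    "residual_statistics",
    "metrics",
    "aggregate_cv",
    "relative_improvement",
    "hybrid_map",
    "cv_map",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
]

log = logging.getLogger(__name__)


def make_folds(n: int, k: int = 10, seed: int = 0) -> np.ndarray:
    """Random fold assignment with the first k-1 folds of size ceil(n/k).

    Returns fold ids 1..k per row. Sizes are (s, ..., s, n - (k-1)s) with
    s = ceil(n/k); n = 398, k = 10 gives nine folds of 40 and one of 38.
    Configurations where the last fold would be empty are rejected.
    """
    if k > n or k < 1:
        raise ValueError("need 1 <= k <= n")
    s = int(np.ceil(n / k))
    last = n - (k - 1) * s
    if last <= 0:
        raise ValueError(f"fold scheme degenerate: n={n}, k={k} leaves {last} rows for the last fold")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f in range(k):
        lo = f * s
        hi = min(lo + s, n)
        folds[perm[lo:hi]] = f + 1
    return folds


def compute_residuals(observed, predicted, fold_of_plot, predicted_by_fold) -> pd.DataFrame:
    """Pooled out-of-fold residuals Z = observed - predicted.

    ``predicted_by_fold`` records which fold's model produced each
    prediction; it must equal the plot's own held-out fold, otherwise an
    in-fold prediction leaked in and the call is rejected.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    fold_of_plot = np.asarray(fold_of_plot)
    predicted_by_fold = np.asarray(predicted_by_fold)
    if not np.array_equal(fold_of_plot, predicted_by_fold):
        bad = int(np.sum(fold_of_plot != predicted_by_fold))
        raise ValueError(f"{bad} prediction(s) are not out-of-fold")
    return pd.DataFrame({
        "observed": observed,
        "predicted": predicted,
        "residual": observed - predicted,
        "fold": fold_of_plot,
    })


def residual_statistics(residuals) -> dict:
    """Moment statistics of the residuals.

    Skewness is m3 / m2^(3/2) and kurtosis is the raw (non-excess) m4 / m2^2,
    so a normal sample sits near 3. With zero variance both are undefined and
    flagged.
    """
    r = np.asarray(residuals, dtype=float)
    if r.ndim > 1:
        r = np.asarray(residuals["residual"] if hasattr(residuals, "columns") else residuals, dtype=float)
    if len(r) < 3:
        raise ValueError("need at least three residuals")
    m = r.mean()
    c = r - m
    m2 = np.mean(c**2)
    out = {
        "mean": float(m),
        "sd": float(np.sqrt(m2 * len(r) / (len(r) - 1))),
        "min": float(r.min()),
        "max": float(r.max()),
        "degenerate": bool(m2 == 0),
    }
    if m2 == 0:
        out["skewness"] = float("nan")
        out["kurtosis"] = float("nan")
    else:
        out["skewness"] = float(np.mean(c**3) / m2**1.5)
        out["kurtosis"] = float(np.mean(c**4) / m2**2)
    return out


def metrics(observed, predicted) -> dict:
    """R^2, RMSE, MAE, Bias and CV% of predictions against observations."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if len(y) < 2 or len(y) != len(yhat):
        raise ValueError("need two or more aligned observations")
    err = yhat - y
    ss_tot = np.sum((y - y.mean()) ** 2)
    rmse = float(np.sqrt(np.mean(err**2)))
    out = {
        "r2": float(1.0 - np.sum(err**2) / ss_tot) if ss_tot > 0 else float("nan"),
        "rmse": rmse,
        "mae": float(np.mean(np.abs(err))),
        "bias": float(np.mean(err)),
        "cv_pct": float(rmse / y.mean() * 100.0) if y.mean() != 0 else float("nan"),
    }
    return out


def aggregate_cv(fold_metrics: pd.DataFrame) -> pd.Series:
    """Arithmetic mean of each metric across folds."""
    return fold_metrics.mean(numeric_only=True)


def relative_improvement(rmse_base: float, rmse_hybrid: float) -> float:
    """RI = (RMSE_base - RMSE_hybrid) / RMSE_base."""
    if rmse_base <= 0:
        raise ValueError("base RMSE must be positive")
    return (rmse_base - rmse_hybrid) / rmse_base


def hybrid_map(base: np.ndarray, kriged_residual: np.ndarray,
               mask: np.ndarray | None = None, clip_zero: bool = False) -> np.ndarray:
    """Cell-wise hybrid composition base + kriged residual under a mask.

    Negative hybrid values are retained by default (``clip_zero`` floors at
    0); cells outside the mask are NaN.
    """
    base = np.asarray(base, dtype=float)
    kr = np.asarray(kriged_residual, dtype=float)
    if base.shape != kr.shape:
        raise ValueError("base and residual rasters have different shapes")
    out = base + kr
    if clip_zero:
        out = np.maximum(out, 0.0)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != base.shape:
            raise ValueError("mask shape mismatch")
        out = np.where(mask, out, np.nan)
    return out


def cv_map(fold_rasters) -> np.ndarray:
    """Per-pixel coefficient of variation (%) across fold-model predictions.

    Population standard deviation (divisor k) over the fold maps, divided by
    the per-pixel mean; pixels with zero mean become NaN.
    """
    stack = np.stack([np.asarray(r, dtype=float) for r in fold_rasters])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(mean != 0, sd / np.abs(mean) * 100.0, np.nan)
    return out


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration."""

    k_folds: int = 10
    n_top_variables: int = 10
    ntree: int = 500
    mtry: int = 3
    nodesize: int = 10
    n_perm: int = 1
    model: EncoderConfig = field(default_factory=EncoderConfig)
    variogram_family: str = "exponential"
    n_lags: int = 12
    glcm_levels: int = 32
    make_maps: bool = True
    loo_diagnostics: bool = True
    clip_hybrid_at_zero: bool = False


@dataclass
class PipelineResult:
    """Artifacts of one full run (tables as DataFrames, maps as 2D arrays)."""

    selected_variables: list[str]
    importance_table: pd.DataFrame
    fold_of_plot: np.ndarray
    fold_r2: pd.DataFrame               # per-fold validation R^2, RF vs CNN-Transformer
    validation_metrics: pd.DataFrame    # averaged metrics per model incl. hybrids + RI
    residuals: pd.DataFrame             # pooled OOF residuals of the CNN-Transformer
    residual_stats: dict
    ok_model: geostat.VariogramModel
    ck_model: geostat.CoregionalizationModel
    variogram_table: pd.DataFrame       # nugget/sill/ratio/range + LOO RMS, RMSS
    feature_table: pd.DataFrame
    maps: dict = field(default_factory=dict)
    seed: int = 0


def _cv_metrics(y, oof_pred, folds) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    for f in np.unique(folds):
        m = folds == f
        rows.append({"fold": int(f), **metrics(y[m], oof_pred[m])})
    per_fold = pd.DataFrame(rows)
    return per_fold, aggregate_cv(per_fold.drop(columns="fold"))


def run_pipeline(scenario: LandscapeScenario, config: PipelineConfig | None = None,
                 seed: int = 0) -> PipelineResult:
    """Execute the full hybrid workflow on a landscape scenario.

    Feature construction -> RF importance screening -> k-fold CV of the RF
    and CNN-Transformer regressors -> pooled OOF residuals -> variogram / LMC
    fits with leave-one-out diagnostics -> OOF-honest hybrid validation (OK
    and CK) -> optional wall-to-wall map products.
    """
    cfg = config or PipelineConfig()
    stage = "feature extraction"
    try:
        fstack = assemble_feature_stack(scenario.stack, glcm_levels=cfg.glcm_levels)
        table = extract_features(fstack, scenario.plots)

        stage = "variable screening"
        rf_screen = fit_rf(table, cfg.ntree, cfg.mtry, cfg.nodesize, seed=seed + 1)
        report = importance(rf_screen, n_perm=cfg.n_perm, seed=seed + 2)
        selected = select_top_k(report, cfg.n_top_variables)

        stage = "cross-validation"
        y = table["agb"].to_numpy(float)
        xsel = table[selected].to_numpy(float)
        n = len(y)
        folds = make_folds(n, cfg.k_folds, seed=seed + 3)
        sub = table[selected + ["agb"]]

        rf_oof = np.empty(n)
        for f in np.unique(folds):
            tr = folds != f
            rf_f = fit_rf(sub.loc[tr], cfg.ntree, cfg.mtry, cfg.nodesize, seed=seed + 100 + int(f))
            rf_oof[~tr] = rf_f.predict(xsel[~tr])

        ct_models = train_cv_ensemble(xsel, y, folds, cfg.model, seed=seed + 4)
        ct_oof = np.empty(n)
        fold_ids = np.unique(folds)
        for i, f in enumerate(fold_ids):
            m = folds == f
            ct_oof[m] = ct_models[i].predict(xsel[m])

        rf_fold, rf_avg = _cv_metrics(y, rf_oof, folds)
        ct_fold, ct_avg = _cv_metrics(y, ct_oof, folds)
        fold_r2 = pd.DataFrame({
            "fold": rf_fold["fold"],
            "rf_r2": rf_fold["r2"],
            "cnn_transformer_r2": ct_fold["r2"],
        })

        stage = "residual geostatistics"
        residuals = compute_residuals(y, ct_oof, folds, folds)
        res = residuals["residual"].to_numpy()
        stats = residual_statistics(res)
        pts = table.reset_index().merge(
            scenario.plots[["plot_id", "x", "y"]], on="plot_id", how="left"
        )[["x", "y"]].to_numpy(float)
        elev = table["elevation"].to_numpy(float)

        emp = geostat.empirical_semivariogram(pts, res, n_lags=cfg.n_lags)
        ok_model = geostat.fit_variogram(emp, cfg.variogram_family)
        ck_model = geostat.fit_lmc(pts, res, elev, cfg.variogram_family, n_lags=cfg.n_lags)
        if cfg.loo_diagnostics:
            ok_rms, ok_rmss = geostat.loo_diagnostics(ok_model, pts, res)
            ck_rms, ck_rmss = geostat.loo_diagnostics(ck_model, pts, res,
                                                      secondary_points=pts, secondary_values=elev)
        else:
            ok_rms = ok_rmss = ck_rms = ck_rmss = float("nan")
        vt = pd.DataFrame([
            {"model": "OK", "family": ok_model.family, "nugget": ok_model.nugget,
             "sill": ok_model.sill, "nugget_sill": ok_model.nugget_sill_ratio,
             "range_m": ok_model.effective_range, "rms": ok_rms, "rmss": ok_rmss},
            {"model": "CK", "family": ck_model.family, "nugget": ck_model.primary.nugget,
             "sill": ck_model.primary.sill, "nugget_sill": ck_model.primary.nugget_sill_ratio,
             "range_m": ck_model.effective_range, "rms": ck_rms, "rmss": ck_rmss},
        ])

        stage = "hybrid validation"
        ok_hybrid = np.empty(n)
        ck_hybrid = np.empty(n)
        for f in fold_ids:
            tr = folds != f
            va = ~tr
            kr = geostat.ordinary_kriging(ok_model, pts[tr], res[tr], pts[va])
            ok_hybrid[va] = ct_oof[va] + kr.predictions
            ckr = geostat.co_kriging(ck_model, pts[tr], res[tr], pts, elev, pts[va])
            ck_hybrid[va] = ct_oof[va] + ckr.predictions
        ok_fold, ok_avg = _cv_metrics(y, ok_hybrid, folds)
        ck_fold, ck_avg = _cv_metrics(y, ck_hybrid, folds)

        val = pd.DataFrame([
            {"model": "RF", **rf_avg.to_dict(), "ri": np.nan},
            {"model": "CNN-Transformer", **ct_avg.to_dict(), "ri": np.nan},
            {"model": "CNN-Transformer-OK", **ok_avg.to_dict(),
             "ri": relative_improvement(ct_avg["rmse"], ok_avg["rmse"])},
            {"model": "CNN-Transformer-CK", **ck_avg.to_dict(),
             "ri": relative_improvement(ct_avg["rmse"], ck_avg["rmse"])},
        ])

        result = PipelineResult(
            selected_variables=selected,
            importance_table=report.table,
            fold_of_plot=folds,
            fold_r2=fold_r2,
            validation_metrics=val,
            residuals=residuals,
            residual_stats=stats,
            ok_model=ok_model,
            ck_model=ck_model,
            variogram_table=vt,
            feature_table=table,
            seed=seed,
        )

        if cfg.make_maps:
            stage = "map composition"
            result.maps = _make_maps(scenario, fstack, selected, xsel, y,
                                     ct_models, fold_ids, ok_model, ck_model,
                                     pts, res, elev, cfg, seed)
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline failed during {stage}: {exc}") from exc


def _make_maps(scenario, fstack: RasterStack, selected, xsel, y, ct_models,
               fold_ids, ok_model, ck_model, pts, res, elev,
               cfg: PipelineConfig, seed: int) -> dict:
    """Wall-to-wall products: base map from a model retrained on all plots,
    kriged residual surfaces, hybrid maps and the fold-variation (CV%) map."""
    grid = scenario.grid
    pix = np.stack([fstack[v].ravel() for v in selected], axis=1)
    valid = np.all(np.isfinite(pix), axis=1)

    final = build_and_train(xsel, y, cfg.model, seed=seed + 5)

    def predict_raster(model: TransformerRegressor) -> np.ndarray:
        out = np.full(pix.shape[0], np.nan)
        out[valid] = model.predict(pix[valid])
        return out.reshape(grid.shape)

    base = predict_raster(final)
    qx, qy = grid.all_centers()
    queries = np.stack([qx.ravel(), qy.ravel()], axis=1)
    okr = geostat.ordinary_kriging(ok_model, pts, res, queries)
    ok_res_map = okr.predictions.reshape(grid.shape)
    elev_pix = scenario.stack["DEM"].ravel()
    ckr = geostat.co_kriging(ck_model, pts, res, pts, elev, queries)
    ck_res_map = ckr.predictions.reshape(grid.shape)

    mask = np.isfinite(base)
    fold_maps = [predict_raster(m) for m in ct_models]
    return {
        "base": base,
        "ok_residual": ok_res_map,
        "ck_residual": ck_res_map,
        "ok_hybrid": hybrid_map(base, ok_res_map, mask, cfg.clip_hybrid_at_zero),
        "ck_hybrid": hybrid_map(base, ck_res_map, mask, cfg.clip_hybrid_at_zero),
        "ok_variance": okr.variance.reshape(grid.shape),
        "ck_variance": ckr.variance.reshape(grid.shape),
        "cv_pct": np.where(mask, cv_map(fold_maps), np.nan),
    }
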