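# agbmap

Hybrid deep-learning + geostatistical mapping of forest aboveground
biomass (AGB).

Regional AGB maps built from optical and SAR imagery inherit two chronic
problems: spectral signals saturate in high-biomass stands, and regression
models ignore the spatial autocorrelation left in their residuals by
unobserved environmental drivers. `agbmap` implements a workflow that
addresses both for users who need wall-to-wall biomass surfaces from
multi-source rasters and sparse inventory plots: a 50-variable predictor
universe (reflectance bands, vegetation indices, principal components,
GLCM textures, SAR polarization features, terrain) is screened by
Random-Forest importance; a 1D CNN-Transformer regresses plot AGB on the
top predictors; and the spatially structured part of its cross-validated
residuals is added back by Ordinary or co-Kriging (elevation as the
co-variable):

    C_hybrid(x) = C_CNN-T(x) + Z_kriged(x),
    Z(x_i) = C(x_i) - C_CNN-T(x_i)   (always out-of-fold)

with residual structure summarized by an exponential semivariogram
γ(h) = c0 + c·(1 − e^(−3h/R)). Evaluation is ten-fold cross-validation
(R², RMSE, MAE, Bias, CV%) plus the relative improvement
RI = (RMSE_base − RMSE_hybrid)/RMSE_base and leave-one-out kriging
diagnostics (RMS, RMSS).

Because inventory plot data are typically confidential, the package ships
a synthetic-landscape generator (`agbmap.synthetic`) that reproduces the
statistical regime such studies report — AGB ≈ 37–185 t/ha, systematic
plot sampling, saturating spectral responses that shift along the
altitudinal gradient, and residuals with nugget/sill ≈ 0.9 at a range of
a few plot spacings — so the whole pipeline is testable end to end.
See `docs/methods.md` for the models and every default.

## Worked example

```python
from agbmap import build_scenario, run_pipeline, PipelineConfig

scenario = build_scenario(seed=1)           # 128x128 @ 100 m, 400 plots
result = run_pipeline(scenario, PipelineConfig(), seed=1)
print(result.selected_variables)
print(result.validation_metrics.round(4).to_string(index=False))
print(result.variogram_table.round(2).to_string(index=False))
```

prints (seed 1):

```
['elevation', 'HV', 'HH', 'PC1', 'HH/HV', 'B11', 'B3', 'mean33', 'RVI_radar', 'B7']
             model     r2    rmse     mae    bias  cv_pct     ri
                RF 0.5909 15.2242 12.3026 -0.1777 15.7264    NaN
   CNN-Transformer 0.6336 14.3841 11.6541 -0.4474 14.8673    NaN
CNN-Transformer-OK 0.6367 14.3117 11.5750 -0.0170 14.7888 0.0050
CNN-Transformer-CK 0.6424 14.1732 11.5053 -0.0107 14.6390 0.0147
model      family  nugget   sill  nugget_sill  range_m   rms  rmss
   OK exponential  196.14 212.93         0.92  5780.46 14.43  1.00
   CK exponential  196.14 212.93         0.92  5780.46 14.32  1.01
```

Reading the output: the Random Forest explains ~59% of held-out plot AGB
variance; the CNN-Transformer improves that to ~63% (RMSE 14.4 t/ha). The
residual variogram says 92% of the residual variance is spatially
unstructured (nugget/sill 0.92) with the remainder correlated out to
~6 km, so kriging the residuals buys a small but consistent improvement —
the CK hybrid shaves the RMSE and removes the bias almost entirely, with
RI ≈ 0.015. LOO RMSS ≈ 1.0 says the kriging variance is well calibrated.
Elevation ranking first among the 50 candidates reflects the altitudinal
shift of the spectral responses built into the landscape. (Exact numbers
vary slightly with the seed; the model ordering RF < CNN-Transformer ≤
hybrids is stable.)

The same workflow is scriptable from the shell:

```bash
agbmap simulate --seed 7 --out-dir runs/sim
agbmap run-all  --seed 7 --out-dir runs/full      # all stages + GeoTIFF maps
agbmap extract --stack runs/sim/covariates.tif --plots runs/sim/plots.csv --out-dir runs/feat
```

Rasters are float32 GeoTIFFs (georeferencing in ModelPixelScale/
ModelTiepoint tags), plots and tables are CSV, configuration and run
manifests are YAML; a run is reproducible from its manifest alone.

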