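# ensorc

Soft sensors for multivariate process time series, built on **ensemble
sparse online next-generation reservoir computing (EnSO NG-RC)**.

Wastewater treatment plants must track effluent quality variables — BOD,
COD, total nitrogen, total phosphorus — that are expensive or slow to
measure directly, while cheap signals (influent loads, flow rate,
suspended solids) stream in continuously. A *soft sensor* predicts the
hard-to-measure targets from the easy ones. `ensorc` implements a family
of such sensors for anyone doing environmental process monitoring or, more
generally, multi-output regression on drifting, noisy sensor streams.

## The model

NG-RC replaces the random reservoir of classical reservoir computing with
a deterministic feature vector built from delayed inputs and their
polynomial products. With auxiliary variables `u_t ∈ R^M`, k time taps at
stride s and library order p, the total feature vector is

    H_total(t) = [1; H_lin(t); H_nlin(t)],
    H_lin(t)  = [u_t; u_{t−s}; …; u_{t−(k−1)s}],
    H_nlin(t) = all unique monomials of H_lin(t) of degree 2…p,

and only the linear readout `W_out` is trained:

    W_out = Y Hᵀ (H Hᵀ + λ₂ I)⁻¹      (ridge least squares).

Three extensions are composed on top:

* **Online updating.** Keeping Φ = (H Hᵀ + λ₂ I)⁻¹, the Woodbury matrix
  identity turns each newly measured block `H_b, Y_b` into an exact
  rank-update,

      Φ′ = Φ − Φ H_b (I + H_bᵀ Φ H_b)⁻¹ H_bᵀ Φ,
      W′ = W + (Y_b − W H_b) H_bᵀ Φ′,

  so the streamed weights equal a full batch refit to round-off — no
  retraining cycle, no extra hyperparameters.
* **Ensemble sparsification.** Sequential thresholded least squares
  (STLS, as in SINDy) zeroes coefficients with |w| < λ₁ and refits on the
  survivors; running it on q bootstrap resamples gives each coefficient an
  *inclusion probability* p_ip, and coefficients with p_ip < λ₃ are
  removed. Bagging makes the recovered support far less noise-sensitive
  than a single STLS pass.
* **EnSO.** The ensemble fit on the initial window fixes the support;
  subsequent blocks update each output row *within* its support by the
  exact online recursion.

Prediction quality is scored per target by MAE, RMSE and Pearson
correlation, and overall by the root mean sum of squares of the diagonal,
`RMSSD = sqrt(trace((Y−Ŷ)ᵀ(Y−Ŷ))/n_test)`, plus Taylor-diagram statistics
and box-plot summaries of absolute errors.

## Worked example

Generate a plant-like dataset (six auxiliary variables with seasonality,
drift and autocorrelated noise; effluent COD and BOD targets driven by a
known sparse quadratic map plus noise) and compare the four variants:

```python
import ensorc as e

syn = e.SyntheticSpec(kind="wwtp_like", n=400, seed=7, noise_sigma=0.5, density=0.08)
cfg = e.PipelineConfig(synthetic=syn, variant="ngrc", train_fraction=0.6,
                       ridge=1e-6, lambda1=0.1, lambda3=0.6, q=50, seed=7)
print(e.compare_variants(cfg, ["ngrc", "online", "ens", "enso"]).round(3).to_string(index=False))
```

```
variant  target   mae  rmse   pcc  rmssd  rmssd_reduction_vs_base
   ngrc cod_eff 3.348 4.334 0.880  4.554                    0.000
   ngrc bod_eff 1.091 1.397 0.903  4.554                    0.000
 online cod_eff 3.000 3.878 0.905  4.040                    0.113
 online bod_eff 0.891 1.131 0.934  4.040                    0.113
    ens cod_eff 2.748 3.508 0.926  3.750                    0.177
    ens bod_eff 1.019 1.325 0.911  3.750                    0.177
   enso cod_eff 2.609 3.268 0.935  3.442                    0.244
   enso bod_eff 0.845 1.083 0.939  3.442                    0.244
```

Errors are in the targets' physical units (mg/L): the dense batch readout
(`ngrc`) overfits its 91-term quadratic library to 240 training samples;
online adaptation, sparsification, and their combination (`enso`) cut the
overall RMSSD by 11%, 18% and 24% here. The same workflow is available
from the shell:

```
ensorc simulate --kind wwtp_like --n 400 --seed 7 --out plant.csv
ensorc fit --data plant.csv --aux cod_in,nh3n_in,tp_in,tn_in,ss_in,flow_q \
           --target cod_eff,bod_eff --variant enso --outdir run/
ensorc compare --data plant.csv --aux cod_in,nh3n_in,tp_in,tn_in,ss_in,flow_q \
               --target cod_eff,bod_eff
```

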