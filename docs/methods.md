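# Methods

This note records the modeling assumptions, numerical choices and known
limitations behind `ensorc`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Model

A soft sensor maps easily measured auxiliary variables `u_t ∈ R^M` to
target quality variables `y_t ∈ R^L` sampled on the same regular grid.
The NG-RC feature vector at time t stacks a constant, the delay embedding
`[u_t; u_{t−s}; …; u_{t−(k−1)s}]`, and every unique monomial of those
`M·k` linear features of total degree 2…p (combinations with repetition,
ordered by degree then lexicographically by index tuple — the order is
part of the public contract, since weight vectors and inclusion
probabilities are reported per feature). The readout is linear,
`ŷ_t = W_out H_total(t)`, trained by ridge least squares. Columns inside
the warm-up `s·(k−1)` are dropped, never padded: every feature column is a
function of samples at its own time or earlier, which is what makes the
leakage audit in the test suite meaningful.

Assumptions worth stating: a fixed sampling interval; targets are a
(possibly slowly drifting) function of current and recent auxiliaries;
one-step-ahead operation (the sensor estimates y at the current time from
inputs up to that time). Free-running multi-step generation is out of
scope. By default the targets' own past values are *not* fed back as
inputs; a user can include them simply by listing a target among the
auxiliary columns.

## Online recursion

With `Φ = (H Hᵀ + λ₂ I)⁻¹` maintained alongside `W`, a new block is folded
in by the Woodbury identity (see `training.update_online`). The recursion
is algebraically exact: any partition of the data into blocks yields the
batch ridge solution on the concatenation. Two hygiene measures keep it
exact in floating point over long streams: the inner `(I + H_bᵀΦH_b)⁻¹` is
applied through a linear solve rather than an explicit inverse, and Φ is
re-symmetrized after every update. The initial Gram is regularized
(`H₀H₀ᵀ + λ₂I`) so initialization is well-posed even when the initial
window is shorter than the feature dimension; the online/batch
equivalence is then an equivalence of *ridge* solutions. There is no
forgetting factor: all history is weighted equally, matching the
derivation; exponential forgetting is a deliberate non-goal.

## Sparsification and the ensemble

STLS starts from the dense ridge fit and runs a fixed number of sweeps
(default 10): zero every |w| < λ₁, then refit each output row by ridge
least squares on its surviving features. Refits use λ₂ for conditioning.
A row whose support empties is returned all-zero with a warning, not an
exception — in ensemble members this is expected noise (and is the correct
answer when a target genuinely depends on nothing in the library).

The ensemble draws q bootstrap resamples of whole time-point columns
(i.i.d. with replacement; a temporal block bootstrap would respect
autocorrelation better and is noted as future work), runs dense-fit+STLS
on each, and computes per-coefficient inclusion probabilities. The final
support keeps `p_ip ≥ λ₃`; final coefficient values come from a full-data
ridge refit restricted to that support per output row, which avoids the
downward bias of averaging bootstrap coefficients (the ensemble-mean rule
is available behind `coef_rule="mean"`). Inclusion probabilities are per
coefficient, not shared across output rows.

EnSO composes the two: the ensemble fit on the initial window fixes the
support, then each output row maintains its own reduced-dimension online
state over its surviving features. This keeps the recursion exact on the
restricted model — the streamed row equals the restricted batch ridge
solution on all data seen — while off-support entries are structurally
zero. Optional re-sparsification every r blocks reruns the ensemble on
all data seen (this requires buffering the stream and is off by default).

## Preprocessing and variable selection

Outliers: a Hampel filter (rolling median/MAD, flag at
`|x−med| > n_sigmas·1.4826·MAD`, default window 7, 3 sigmas), applied to
the training span only; flagged points are replaced by the rolling
median, and windows with MAD = 0 flag nothing. Caveat: with small windows
the rolling MAD is a noisy scale estimate, so the effective false-flag
rate on white noise is a few percent at window 7 and only approaches the
nominal ~0.3% for windows ≳ 25–50. The filter is meant to excise isolated
spikes, for which small windows are fine; for calibrated flagging rates
use a wider window.

Standardization is fit on the training span and reused verbatim on the
test span. Optional lag differencing `x′_t = x_t − x_{t−lag}` (default lag
1 when enabled) is causal and exactly invertible; predictions are mapped
back to the original scale using the measured targets at `t−lag`, which a
plant historian has by the time the prediction is scored. The pipeline
order is outliers → differencing → standardization, so the scaler
normalizes whatever actually enters the feature builder.

Variable selection combines PLS-VIP scores (`VIP_j ≥ 0`,
`mean(VIP²) = 1`, component count chosen by leave-one-out prediction
error when not given) with LASSO selection. The LASSO penalty is chosen by
5-fold CV with the one-standard-error rule, followed by thresholded-lasso
pruning of coefficients below 5% of the largest — the CV-error minimizer
alone is known to over-select. At penalty exactly 0 the fit is OLS and all
variables are selected (no shrinkage remnants to prune). Rules for
combining the two screens: union (VIP > 1 or LASSO-selected, the
default), intersection, or pure VIP rank; a domain list is always
retained, and a target cardinality trims by VIP rank — mirroring how
plants reduce a candidate pool to a handful of auxiliaries.

## Evaluation

Metrics are computed on the original physical scale after undoing
standardization and differencing, since regulatory limits and plant
reports live there. RMSSD is the overall multi-output error
`sqrt(trace(EᵀE)/n_test)`; it equals RMSE for one target and satisfies
`RMSSD² = Σ_targets RMSE²`. Taylor statistics use `ddof=1` consistently so
the law-of-cosines identity `cRMSE² = σ_ref² + σ_pred² − 2σ_refσ_predρ`
holds to round-off. Absolute-error boxes follow the Tukey 1.5·IQR
convention. Pearson correlation on a constant series is reported as
missing (NaN) with a warning rather than an arbitrary value. Plots are
not rendered; the statistics that would feed them are reported as
numbers.

## Synthetic benchmarks

`gen_chaotic` integrates Lorenz-63 (σ=10, ρ=28, β=8/3) with fixed-step
RK4, discards a 1000-step transient, and pairs each state with its
one-step successor. The default benchmark uses dt = 0.025 and n = 2000
(1200 train / 800 test) — the step is small enough that the quadratic
k=2 library approximates the RK4 one-step map far below the 1e-3 NRMSE
level the tests require.

`gen_planted_sparse` draws i.i.d. standard-normal inputs (a deliberately
well-conditioned polynomial Gram), a sparse readout with coefficient
magnitudes in [0.5, 1.5] at the requested density, and adds Gaussian
noise. Because targets are driven, not fed back, trajectories cannot
explode; a norm guard with rescaling exists for any future autoregressive
mode. The support-recovery experiments use a 12-feature linear library
(constant + 11 inputs, 20% density, n=500), the identification and
streaming-exactness experiments use the quadratic library (d=45) and a
30-feature linear library (d=30, n=300) respectively — sizes chosen so the
whole acceptance script completes in seconds.

`gen_wwtp_like` emulates the shape of plant data: six auxiliaries
(influent COD, NH₃-N, TP, TN, SS, flow) with seasonal sinusoids, slow
drift (trend + bounded random walk), AR(1) noise, on physically plausible
scales; targets apply a known sparse degree-2, two-tap polynomial map to
the internally standardized auxiliaries. Since that map is polynomial of
degree ≤ 2 in an affine transform of the inputs, the k=2, p=2 library
with a constant represents it exactly under any re-centering — giving both
a correct-model-class regime and, with p=1, a misspecified one. Optional
spike outliers are injected at a stated rate and magnitude with masks
retained. What this generator does *not* emulate: missing-data gaps,
changepoints, genuinely time-varying target maps, or mechanistic
activated-sludge dynamics — so passing tests demonstrate algorithmic
correctness and the claimed robustness mechanisms, not plant-scale
accuracy.

The overfitting benchmark (noise σ = 0.5 in standardized target units,
n = 400 with a 60% train split, density 0.08) puts the dense 91-term
quadratic readout on 240 training samples — the regime the sparse
ensemble exists for.

## Defaults

| Parameter | Default | Meaning |
|---|---|---|
| k (`n_delays`) | 2 | delay taps |
| s (`spacing`) | 1 | tap stride (samples) |
| p (`poly_order`) | 2 | highest monomial degree |
| λ₂ (`ridge`) | 1e-6 | readout regularization |
| λ₁ (`lambda1`) | 0.1 | STLS threshold (standardized scale) |
| λ₃ (`lambda3`) | 0.6 | inclusion-probability threshold |
| q | 50 | bootstrap members |
| `stls_iters` | 10 | STLS sweeps |
| block size | 1 | online update granularity |
| train fraction | 0.6 | chronological split |

These are documented working defaults for standardized data, not claims
about any particular plant; λ₁ in particular should be tuned on a
validation split when target maps have small true coefficients. The
chronological split and the predict-then-update test protocol (each test
block is predicted before its true targets are folded in) are fixed
design choices, as is adapt-on-test defaulting to on for the online
variants — turning it off makes the online variant coincide with the
batch fit exactly.

## Known limitations

Coefficient-wise thresholds act on the standardized scale and are not
invariant to feature rescaling; the library grows combinatorially in
`M·k` and p (the dense solve is O(d³)); inclusion probabilities are
bootstrap frequencies, not posterior probabilities; the i.i.d. bootstrap
understates uncertainty under strong autocorrelation; and the exact
online/batch equivalence holds for the ridge solution with the λ₂ baked
in at initialization — changing λ₂ mid-stream requires re-initialization.
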