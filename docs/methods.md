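# Methods

This note documents the models, the synthetic study conditions, the
numerical choices and the known limitations of `printopt`.

## Problem setting

A printlet is a cylindrical 3D-printed dosage form (10 mm diameter,
5 mm height; 25 layers at 0.2 mm layer height). Its quality is scored
by the *percentage surface defect*: the fraction of printlet pixels in a
top-view photograph classified as voids. Four FDM process parameters are
varied — print speed (mm/s), infill density (%), print temperature (°C)
and volumetric flow rate (mm³/s) — with two printer profiles:

| constant | batch | continuous |
|---|---|---|
| KRR regularization λ | 0.5 | 0.7 |
| void gray threshold | 0.45 | 0.35 |
| forest (trees/depth/feat/split/leaf) | 400/160/2/4/1 | 2000/50/4/12/3 |

All defect values are carried internally as fractions in [0, 1];
percent appears only in printed reports.

## Image segmentation

Photographs are converted to grayscale (luma weights 0.299/0.587/0.114
for RGB) and rescaled to [0, 1]; the 0.45/0.35 void thresholds are on
this normalized scale. The printlet mask is the largest connected
component above an automatic Otsu threshold, with interior holes filled
so that voids count in the denominator ("voids and non-voids"). A pixel
is a void when its gray value is *strictly below* the void threshold;
the strict inequality is a convention and only affects measure-zero
boundary cases. Failed automatic segmentations can be rescued with a
user-supplied region-of-interest crop instead of manual background
editing. The measured fraction is monotone in the void threshold and
invariant under affine gray rescaling applied to both image and
threshold.

## Data scaling and splitting

Features are standardized per column, `x_new = (x − μ)/σ`, with the
**population** (divisor n) standard deviation — the convention of common
scaler implementations; the divisor choice was open and is fixed here
once. Test data is always scaled with the training μ, σ. The 80:20
split is row-level (replicates of one combination may land on both
sides) because the study counts individual replicate samples entering
the split; group-level splitting can be emulated by splitting the
design before measurement when leakage matters.

## Kernel ridge regression

Polynomial kernel `(γ⟨x, x'⟩ + c)^d`, defaults d = 3, c = 0.2,
γ = 1/n_features. The single stated "coefficient 0.2" is read as the
additive constant c — the conventional polynomial-kernel
parameterization — with γ exposed separately. The dual system
`(K + λI) w = y` is solved by Cholesky factorization with jitter
escalation (0 → 1e-10 → 1e-8 → 1e-6), never an explicit inverse.
Hyperparameters come from 10-fold cross-validated grid search
(mean-MSE argmin; ties toward smaller λ, then lower kernel index).
Metrics: R² = 1 − SSE/SST, MAE, RMSE, computed at replicate (row)
level.

## Random forest and MDI importance

Trees are standard CART: greedy variance-reduction splits over a random
feature subset per node, candidate thresholds at midpoints between
consecutive distinct sorted values, ties broken toward the lowest
feature index then the lowest threshold. Node impurity C_k is the mean
squared deviation of the node's targets and W_k the fraction of the
tree's training samples reaching the node, so the node contribution
`F_jk = W_k C_k − W_l C_l − W_r C_r` is the usual weighted impurity
decrease. The per-tree normalizer sums F over **all internal nodes of
the same tree**, making importances sum to one as conventionally
reported. Bootstrap resampling is on by default. A deterministic
full-feature tree reproduces scikit-learn's `DecisionTreeRegressor`
splits, predictions and importances exactly; that library is used only
as a cross-check, never as the implementation.

## Gaussian process and Expected Improvement

Zero prior mean; covariance `exp(−θ‖x − x'‖²) + δ(x,x')σₙ`. The
covariance has no amplitude parameter, so the prior amplitude is fixed
at 1 and targets are standardized before fitting (destandardized for
reporting). θ and σₙ are selected on the grids θ ∈ {0.01, 0.03, 0.1,
0.3, 1, 3}, σₙ ∈ {1e-6, 1e-4, 1e-2, 1e-1} by maximizing the log
marginal likelihood (Cholesky-based; ties toward smaller θ, then
smaller σₙ). Predictions are the latent-function posterior; variances
are clipped at zero before the square root.

Expected Improvement is the minimization form with the exact σ → 0
limit `max(μ* − μ, 0)`. Selection orders candidates by EI, then by
lower posterior mean, then by index: the mean tie-break implements pure
exploitation when all uncertainties vanish (otherwise an all-zero EI
vector would degenerate to "first candidate wins").

`candidate_probability` reports the Gaussian posterior mass within
±tolerance of the target, `Φ((t+tol−μ)/σ) − Φ((t−tol−μ)/σ)` — a
documented stand-in for a per-candidate success probability, since no
canonical construction exists for deriving one from a model-level R².

## Adaptive loop

Nonzero targets are optimized through the deviation objective
`|defect − target|`; μ* is the smallest deviation measured so far. Per
iteration the accumulated features are re-standardized (a constant
column gets σ = 1 rather than an error, so a degenerate mid-run state
cannot crash the loop), the GP is refitted, already-evaluated grid
points are excluded, and the EI argmax is evaluated and appended — one
row per iteration, exactly. Stopping: a measured defect within
tolerance of the target ("target-met"), the evaluation budget
("budget-exhausted"), or an exhausted candidate grid
("space-exhausted"). The default candidate grid spans speed 10–50,
infill 5–40, temperature 180–220, flow 20–120, all in steps of 5
(13 608 points).

## Synthetic study conditions

The virtual printer's response surface is

    defect = base + A·logistic((knee − flow)/width)
           + a_s·|speed − 30| + a_i·(100 − infill)/100 + a_t·|temp − 200|

clipped to [0, 1], with base 0.003, A 0.4, knee 90 mm³/s, width 5 mm³/s,
a_s 5·10⁻⁴ per mm/s, a_i 0.005, a_t 4·10⁻⁴ per °C, and Gaussian
replicate noise of sd 0.015 (the ~1–2% absolute level of image-based
defect readings). These values encode the qualitative physics: prints
at ≤ 80 mm³/s are badly under-extruded (~35–40% defects), ≥ 110 mm³/s
prints are clean, the other three factors matter far less, and the true
optimum (~0.7% defect at speed 30, infill 40, temp 200, flow 120) is
genuinely reachable, as defect-free prints are in practice. On this
surface the flow rate carries ~0.99 of the MDI importance — more
extreme than the ~0.8 share a real printer shows, because the three
minor factors are given physically small, noise-dominated effects;
qualitative checks therefore assert dominance (≥ 0.5), not the exact
share.

The virtual camera renders a bright disc (gray 0.8) on a dark
background (0.15) with dark voids (0.1) and additive noise (sd 0.02),
levels chosen to straddle the 0.45 threshold with ~17σ margins so
segmentation error reflects geometry, not noise. Voids are
non-overlapping discs (radius 3–7 px) placed by rejection sampling
strictly inside the printlet; after 1000 consecutive rejections overlap
is permitted so generation terminates, and the final void radii shrink
so the achieved fraction lands within ±0.01 of the target (exact
ground-truth masks are returned alongside the image). Not emulated:
uneven illumination, specular texture, perspective, camera blur —
passing tests demonstrate the correctness of the measurement chain, not
robustness to real-world imaging artifacts, which is what the
region-of-interest escape hatch is for.

## Problem sizes

The test suite and the reproduction script run the study at desk scale
chosen for quick iteration: the full 81-combination × 5-replicate table
(405 rows) for surrogate training and importance, 50 rendered images
for segmentation recovery, 20 seeds × 25-evaluation budgets for the
closed loop (30 for the 15% target), and 10–20 random small problems
per oracle comparison.

## Known limitations

* The deviation objective `|d − target|` is kinked at the target, which
  a squared-exponential GP smooths over: when the initial design
  contains no point near the narrow flow band that realizes a nonzero
  target, the likelihood-selected lengthscale can interpolate across
  the valley, EI collapses, and the loop exploits the wrong plateau
  until the budget runs out. Most seeds converge in ≤ 15 evaluations;
  occasional ones do not. Modeling the signed defect and acquiring on
  the target band directly would remove the kink, at the cost of
  departing from the EI-on-deviation design.
* The forest is exact but pure NumPy; the continuous profile
  (2000 trees) takes tens of seconds on 405 rows.
* Printer profiles carry no material (PLA/PVA/TPU) features; the
  surrogates are per-material by construction.
* The two extra design rows of a conveyor-printer study (83 vs 81
  combinations) are not generated; non-factorial designs enter via CSV.
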