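# Methods

## Model

A complex-valued multi-subject fMRI dataset is a three-way tensor
`X ∈ C^{V×J×K}` (in-brain voxels × time points × subjects).  The
shift-invariant CPD model is

    x_{v,j,k} = Σ_r s_{v,r} · b_r(j − τ_{k,r}) · c_{k,r} + e_{v,j,k},

with shared spatial maps `S = [s_1 … s_R]`, shared time courses
`B = [b_1 … b_R]`, subject intensities `C = {c_{k,r}}`, and integer
subject delays `τ_{k,r}` realized as cyclic shifts.  The cyclic-shift
convention is fixed throughout: `shift(b, τ)[j] = b[(j + τ) mod J]`
(left shift for positive τ); the simulator and the estimator share it, so
planted and estimated delays live on the same axis.  The model is
invariant to shifting `b_r` by a constant lag while offsetting all its
delays, so the solver anchors the indeterminacy by keeping each
component's median delay at zero (a pure index relabeling; the cost trace
is unchanged), and the evaluator removes the residual lag before scoring.

## Estimator

Each outer iteration performs four steps:

1. **Spatial maps.** `S ← X_(1) M^{†T} − λ ΔS (M^H M)^{-1}`, where `M` is
   the aggregating mixing matrix built from the current `B, C, τ`
   (row-block k of column r is `shift(b_r, τ_{k,r}) c_{k,r}`).  Before
   the gradient term, each column's arbitrary global phase is resolved on
   a uniform grid of 128 angles by maximizing the squared correlation
   magnitude between the `±π/4`-masked rotated map and its own magnitude
   image.  Because a global phase factor cancels in that magnitude, the
   score depends on the angle only through the masked voxel set, and each
   angle reduces to an O(1) circular-window query over the phase-sorted
   map (the dense mask-matrix evaluation is kept as a test oracle).  The
   per-component phase threshold `θ_th` is recomputed every iteration as
   the `⌈V/3⌉`-th largest absolute phase; the smoothed-l0 gradient is
   `Δs = e^{iθ(s)} (|s|/σ²) e^{−|s|²/2σ²}` on the voxels at or above the
   threshold and exactly zero below it — the analytic derivative of the
   penalty `1 − e^{−|s|²/2σ²}` (verified against central differences).
2. **Orthonormality.** `S ← U D^H` from the economy SVD `S = U Σ D^H`
   (the polar factor, i.e. the Frobenius-nearest semi-unitary matrix).
3. **Mixing matrix.** `M ← (S^† X_(1))^T`; with `S` semi-unitary this is
   `(S^H X_(1))^T` and the product is reused for the cost evaluation.
4. **Per component:** reshape column r of `M` to a `J×K` matrix; update
   every subject's delay by maximizing `Re⟨m_{r,k}, c_{k,r}
   shift(b_r, τ)⟩` over `|τ| ≤ max_delay` via one FFT cyclic
   cross-correlation (exactly equal to exhaustive search; ties prefer the
   smallest |τ|, then negative); refit `b_r` per Fourier index in closed
   form (`FFT(shift(b, τ)) = e^{+i2πfτ/J} FFT(b)`), normalize, refit and
   normalize `c_r`.

σ is annealed as `σ ← γσ` per iteration.  Convergence is declared when
the relative change of the cost falls below `ε`, or immediately when the
residual reaches the numerical floor (`≤ 1e−14` of the data power, which
a relative criterion alone never certifies on exactly decomposable data).
The cost is the mean squared residual plus `λ` times the voxel-averaged
penalty; it is evaluated from Gram matrices (`‖X‖², S^H X_(1), S^H S,
M^H M`) so no dense residual tensor is formed at full scale.  The
printed-norm residual variant (mean |residual|) is computed once for the
returned solution (`FitReport.final_fit_abs`).  Restarts draw independent
complex-normal `B, C` from child seeds of the master seed; the best final
cost wins, and runs whose cost grows beyond 10× the initial value are
discarded.  With all three constraint toggles off, the iteration reduces
to the unconstrained alternating rank-R/rank-1 rule (`run_arr_r1ls`
shares the same code path, so the trajectories are bitwise identical).

### Parameters (defaults)

| parameter | default | meaning |
|---|---|---|
| `lam` (λ) | 4 | weight of the phase-sparsity penalty |
| `sigma0` (σ₀) | 2 | initial smoothed-l0 width, in SM magnitude units |
| `gamma` (γ) | 0.99 | per-iteration annealing factor, 0.9 < γ < 1 |
| `n_angles` | 128 | phase de-ambiguity grid resolution |
| `max_delay` | 10 | delay search half-window (samples) |
| `eps` | 1e−6 | relative cost-change convergence threshold |
| `iter_max` | 200 | outer iteration cap |
| `n_runs` | 20 | random restarts (studies here use 5 where noted) |

λ, σ₀, γ and the ±10-sample window are the package's standard study
configuration; note that σ₀ is meaningful only relative to the
spatial-map magnitude scale (see the simulator's amplitude below).

## Synthetic data generator

The generator emulates a SimTB-style task experiment rather than
re-implementing SimTB: spatial sources are analytic anisotropic Gaussian
blobs on a 100×100 grid restricted to an elliptical in-brain mask of
exactly 7688 cells (the cells of smallest elliptical radius, so the
count is exact by construction).  Source width scales with the in-brain
area available per component — σ uniform on
`[0.22, 0.35]·sqrt(V/R)` voxels, capped at 8–13% of the grid side for
small grids — with aspect ratio ≤ 1.25, and centers are drawn in the
mask interior with a minimum separation of 1.6× the maximum width
(stochastically relaxed when the packing is tight).  This mimics an
anatomical parcellation: sources tile the brain with moderate overlap
instead of stacking on top of each other, which is also the regime in
which a rank-R decomposition of 30 sources is identifiable at all.  The task time
course is a 40 s on / 30 s off boxcar (on first) convolved with a
canonical double-gamma HRF (peak 6 s, undershoot 16 s, ratio 1/6) at
TR = 2 s; nuisance time courses are Gaussian white noise smoothed with a
2-sample Gaussian kernel; all time courses are unit-norm.  Subject
intensities are uniform on [0.5, 1.5]; delays are integers uniform on
[−10, 10].  Activated voxels (above half-max magnitude) carry i.i.d.
phases uniform on [−π/18, π/18]; the background phase field (uniform on
[−π, π]) is drawn once per component and shared by that component's
subject variants — the non-activated phase pattern is treated as a
property of the source, and per-subject redraws would decorrelate the
subjects' complex maps in a way the shared-map model never assumes.
Subject variability redraws, per subject and component, a translation
uniform on ±3 voxels per axis, a rotation uniform on ±30°, and a spread
factor uniform on 1 ± 0.12, applied analytically to the blob.  With all
three variability ranges zero, every subject reuses the canonical complex
map exactly, so the clean tensor is exactly rank-R — the regime used for
the noiseless recovery checks.

The source peak magnitude defaults to 10.  The solver's unit-norm TC and
intensity convention pushes the whole data scale into the spatial maps,
and the smoothed-l0 defaults (σ₀ = 2, λ = 4) presuppose activated
magnitudes well above σ₀ — with order-1 sources every voxel sits in the
linear-shrink regime where the step `λ/σ²` exceeds 1 and the update
over-shrinks.  An amplitude of 10 puts activation an order of magnitude
above the annealing start, the regime the stated defaults are designed
for.

Noise is circular complex Gaussian, scaled so that
`20·log10(σ_s/σ_n)` equals the requested SNR, with `σ_s` the pooled
temporal standard deviation of the clean signal and `σ_n` the complex
noise standard deviation (`E|n|² = σ_n²`); the generator reproduces
requested SNRs to within 0.1 dB (tested).

What the generator does **not** emulate: SimTB's exact source geometries
(rings, crescents, multi-lobe shapes), physiological nuisance structure
(drift, motion, cardiac/respiratory signals), spatially correlated noise,
and magnitude/phase noise coupling of real k-space data.  Tests passing
on this generator therefore demonstrate correctness of the estimator
under the stated generative model, not performance on real scanners'
data.

## Evaluation

Components are matched to references by an optimal assignment (Hungarian
algorithm) maximizing summed SM-magnitude |ρ| (absolute Pearson
correlation); matching is invariant to component order and complex column
scaling.  Per matched pair: SM magnitude |ρ|; SM phase score = |ρ|
between the estimate's ±π/4 phase mask and the reference activation
mask; TC magnitude and unwrapped-phase |ρ| after removing the circular
lag that maximizes |⟨shift(b_est, d), b_ref⟩|; intensity magnitude |ρ|;
delay metrics on the lag-compensated integer delays (exact-match counts
and the Pearson correlation across subjects, the latter invariant to the
lag).  Estimated activation for the voxel counts (`V_all`, `V_in`,
`V_out`, `V_in/V_all`) uses a z-score threshold of 2.0 on the SM
magnitude — a configurable convention; no published thresholding rule is
claimed.

## Problem sizes used by the checks

The noiseless recovery check runs at V=500, J=80, K=8, R=3 (delays ≤ 5);
the noise-degradation trend at V=1000, J=160, K=10, R=10 with one restart
and 60 iterations per fit, five seeds per SNR at 0/−10/−20 dB; the
simulated task-delay study at the full reference configuration (V=7688,
J=160, K=10, R=30, SNR −10 dB) with best-of-5 restarts and 200
iterations.  These sizes are the package's own choices for routine
verification; the estimator itself has no scale assumptions beyond
memory.

## Numerical choices and edge cases

- Pseudoinverses use an SVD cutoff `max(dims)·eps·σ_max`; rank-deficient
  systems are solved with the thresholded inverse and logged.
- `(·)^{†T}` is the plain (non-conjugating) transpose of the
  pseudoinverse; all conjugation lives inside the pseudoinverse, and
  inner products are conjugate-linear in the first argument.
- Phase de-ambiguity identifies the rotation only up to the slack the
  ±π/4 band leaves around a source's internal phase spread (score ties
  inside the band); ties are broken toward the identity rotation (2π).
  A constant-magnitude map has no defined correlation: the identity is
  returned and flagged.
- The smoothed-l0 penalty reports the constant branch (1 per small-phase
  voxel) but that branch has zero gradient; the penalty's support is
  re-derived from the current phases each iteration.
- Degenerate rank-1 fits (zero b or c) restart from the dominant column
  of the component matrix and are logged.
- Delay ties prefer the smallest magnitude, then negative sign; the
  candidate list drops aliases when the search window exceeds J/2.

## Known limitations

- The delay search assumes cyclic wrap-around; real hemodynamic delays
  are linear shifts, and components with energy at the run boundaries can
  alias.
- Orthonormality is a hard projection; strongly overlapping true sources
  violate it, biasing their magnitude estimates.
- Under strong inter-subject spatial variability the shared-map model is
  itself misspecified; recovered maps approach the variability average
  and the attainable correlations fall with the variability magnitude —
  visible in the reduced-size studies, where the stated ±3-voxel
  translations are large relative to the proportionally smaller sources.
- Delay accuracy degrades when a time course is nearly periodic (the
  block-design period creates near-tied alignment lags); the evaluator's
  lag compensation keeps the delay correlation well-defined regardless.
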