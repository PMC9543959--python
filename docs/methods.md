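# Methods

## Model and procedure

The package analyses trial-structured kinematics: joint angles
`X̃_{i,j,k}` (joint i = 1..I, frame j = 1..J, trial k = 1..K) and one
scalar performance value `d_k` per trial.  The pipeline is:

1. **Per-cell standardization** for regression: each (joint, frame)
   cell is centred and scaled across trials with population (1/K)
   moments, as is `d`.  Zero-variance cells are hard errors rather than
   silently dropped features, because the map's indices must stay
   aligned with the (joint, frame) grid.
2. **Ridge regression** of `d` on the vectorized motion.  The closed
   form `(xᵀx + σ²I)⁻¹xᵀd` is solved in the primal (IJ×IJ) or dual
   (K×K) system, whichever is smaller; the two are algebraically
   identical and the dual is the cheap one in the usual regime
   (IJ = 240 features vs K ≈ 150 trials).  σ² is equivalent to assuming
   i.i.d. Gaussian observation noise of variance σ²/K on each motion
   feature; ridge rather than OLS is essential because neighbouring
   frames of a smooth trajectory are strongly collinear.
3. **Space conversion.**  For module comparison the motion is
   standardized per joint (one mean/sd over all frames and trials), and
   the map converts as `W_{i,j} = (s_i/s_{i,j}) W̃_{i,j}` with constant
   `Σ W̃_{i,j}(m_i − m_{i,j})/s_{i,j}`; the two prediction expressions
   agree on every trial to floating tolerance (asserted in tests).
4. **SVD** of W into task-relevant spatial/temporal modules, per-trial
   performance fragments, and the two contribution curves; conventional
   motion-relevant modules come from the reshaped SVDs of the motion.
5. **Spectral identity.**  The construction
   `w = Σ_r v_r (v_rᵀxᵀd)/(ω_r²+σ²)` over the thin SVD of the
   trial-vectorized motion reproduces the ridge solution exactly for
   σ² > 0 (the solution lies in the row space, so no null-space term is
   needed).  Note that under population standardization the coupling
   `β = xᵀd` equals K times the per-feature Pearson correlation; the
   identity holds with the un-divided β, and both scalings are stored.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `sigma2_grid` | 13 points, 10⁻³..10³ (log) | ridge regularization candidates |
| `folds` | 10 | shuffled trial-level CV folds |
| `rank` | min(I, J) | retained task-relevant modules |
| `n_phases` | 3 | contiguous phase blocks for temporal-module comparison |
| `correction` | bonferroni | multiplicity correction across modules tested |

The CV protocol (shuffled 10-fold, grid-selected σ², standardization
refit per training fold, held-out trials transformed with training
moments) is the package's own choice of a standard protocol; folds and
seed are exposed so any variant is reproducible.

## Synthetic generator

The generator emulates the statistical regime the framework assumes:

* **Band-limited smooth trajectories.**  Temporal structure is drawn in
  a real Fourier basis of 11 modes — the constant plus five harmonic
  pairs, i.e. a 10-Hz band over a 500 ms window — because joint angles
  derived from low-pass filtered motion-capture markers carry no energy
  above the filter cutoff.  Measurement noise is drawn in the same band
  (white frame-level noise does not exist in filtered data).  Complete
  harmonic pairs have flat pointwise energy, which keeps per-cell
  standard deviations uniform across frames; this matters because the
  regression-space → module-space conversion rescales by `s_i/s_{i,j}`,
  and strongly frame-dependent cell sds would obliquely distort any
  recovered map relative to a map planted in the module space.
* **Planted modules.**  Each trial is `Σ_r a_r b_r c_{r,k}ᵀ` with
  random orthonormal spatial modules, geometrically decaying amplitudes
  (ratio 0.7), and per-trial temporal coefficients orthonormalized by
  QR around a shared mean shape (shape variability 0.5 in coefficient
  units).  The signal is scaled to unit element sd so `noise_sd_motion`
  is interpretable as 1/SNR; the default 0.1 is SNR 10.
* **Performance.**  `d_k = ⟨W_planted, X_k⟩ + ε` on the per-joint
  standardized motion; planted temporal modules are drawn in the same
  Fourier band so the map lies in the excited subspace — a task-relevant
  direction the motion never visits is unidentifiable from data by any
  estimator, so identifiable planted maps are the meaningful test bed.
* **Perturbation schedule.**  Zeros for 10 baseline trials, then a
  10-trial linear ramp of 0.005 per trial reaching 0.05, then a constant
  hold (all parameters exposed; the internal consistency 10 × 0.005 =
  0.05 is asserted exactly).
* **Adaptation.**  A single-state error-driven learner
  (`est ← est + 0.2(p − est)`) tracks the perturbation and scales the
  first module's amplitude by `1 − 10·est` (up to −50% at the 0.05
  hold), so the first task-relevant fragment correlates negatively with
  the perturbation while other modules are untouched.  The learner is a
  minimal stand-in whose only job is to give the adaptation statistics
  a known rejection/no-rejection ground truth.

What the generator does **not** emulate: nonlinear body dynamics,
nonstationary fatigue or drift, target-height variation within a
session, inter-joint noise correlations, and realistic joint-angle
units/offsets.  Passing tests therefore demonstrate correctness of the
estimators and statistics under the assumed linear, band-limited,
low-rank regime — not that real jump data satisfy those assumptions.

## Numerical choices

* Population (1/K) moments everywhere, matching the estimator's
  derivation; sample-moment variants are deliberately not offered.
* SVD sign convention: the largest-magnitude element of each spatial
  (or spatiotemporal) module is made positive, with the paired factor
  flipped jointly — deterministic output across platforms, needed for
  across-experiment module comparison.
* σ² = 0 is allowed only with a full-column-rank design; otherwise a
  hard error advises σ² > 0 (the minimizer is not unique).
* Numerically zero singular values (below `max(K,IJ)·eps·ω₁`) are
  dropped from the spectral basis.
* k-fold splits: shuffled permutation, `array_split`, earliest folds
  larger when K is indivisible; the same earliest-blocks-larger rule
  divides temporal modules into phases.
* Zero-variance guards use a relative floor of 1e-12 on standard
  deviations.

## Design decisions that were genuinely open

* **"Variance in the predicted performance explained"** by the first
  r̂ modules is defined as `Var_k(Σ_{r≤r̂} ŷ_{k,r}) / Var_k(Σ_r ŷ_{k,r})`.
  Because fragments are correlated across trials, this curve is not
  guaranteed monotone (and empirically is not in roughly half of
  generator instances); only its terminal value (exactly 1) is a shape
  guarantee.  The two motion-variance curves — cumulative `a_r²` for
  motion-relevant modules and cumulative `λ̂_r = w_r xᵀx w_rᵀ` for
  task-relevant modules — are non-decreasing by construction, since
  their increments are nonnegative quadratic forms.
* **λ̂_r uses the λ_r-weighted map** `w_r = vec(λ_r s_r t_rᵀ)`, not a
  unit-normalized direction, so contributions scale with λ_r²; this
  follows the definition of the quantity being reported rather than a
  variance partition (w_r is not an eigenvector of xᵀx).
* **Per-trial temporal coefficients** are defined by projection,
  `c_{r,k}ᵀ = b_rᵀX_k/a_r`.  Mutual orthogonality of coefficients
  within a trial cannot hold simultaneously with shared spatial modules
  except in the exact planted case; it is asserted only there and is
  approximate otherwise.
* **Motion-module standardization**: the per-joint scheme is the
  default; a column-wise scheme (each column of the unfolded matrix
  standardized across its rows) is available as `std="columnwise"`.
  Both are legitimate readings of standard practice and neither is
  declared "intended"; results should state which was used.
* **Multiplicity correction** defaults to Bonferroni across the modules
  tested within an experiment; Holm and no correction are available and
  the method is always recorded in the output.
* **Trial subset for adaptation correlations** defaults to all trials;
  a `trial_subset` argument restricts to probe or learning trials when
  the design distinguishes them.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the
study geometry (4 × 60, 150–200 trials): 20-seed sweeps for the
prediction-error anchors and subspace recovery, 50 seeds × 13 simulated
subjects for the adaptation power check, and a 1000-replicate
fragment-level null for the family-wise error rate.  These sizes give
stable medians and rates while keeping a full run in well under a
minute for the anchors and a few minutes for the whole suite.

## Known limitations

* With fewer trials than features (K < IJ) the relevance map is
  identified only within the row space of the observed motion; the
  reported map is the minimum-norm/ridge representative, and
  task-relevant directions orthogonal to all observed variation are
  invisible in principle.
* The adaptation simulator's one-state learner produces a monotone,
  deterministic adaptation trace; real adaptation has retention/decay
  dynamics and inter-subject variability that the power figures here do
  not capture.
* The parabola utility `h = p + v²/(2g)` and the planar-chain forward
  kinematics are simulator conveniences, not biomechanically validated
  models.
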