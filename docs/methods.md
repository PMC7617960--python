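# Methods

## The model

The object of interest is the HRV spectrum matrix `S ∈ R^{n_r × n_fr}`:
one row per 5-minute segment of a recording, one column per frequency bin
of the analysis band (0.04–0.4 Hz by default).  Because consecutive
segments of a recording share physiology, and because each PSD is dominated
by two smooth lobes (the Mayer wave in LF and respiratory sinus arrhythmia
in HF), the rows are highly redundant and `S` has rapidly decaying singular
values.  Spectrum regions corrupted by artefacts, missed beats or
interpolation are treated as *missing entries* of `S` and re-estimated
under a low-rank prior.

### Interest-zone completion

Given the observed-entry set Ω, the completion solves

    min ‖A_Ω(X) − A_Ω(S)‖_F   s.t.  ‖X‖ ≤ λ

by alternating two Frobenius projections (a POCS iteration): the projection
onto the norm ball, and the restoration of the observed entries.  Starting
from the zero-filled matrix, the fidelity ε(X) = ‖A_Ω(X) − A_Ω(S)‖_F is
nonincreasing and converges; the iteration at fixed λ is denoted T(S, λ).
The outer driver bisects λ on [0, ‖A_Ω(S)‖_*], treating a bound as feasible
when T reaches ε ≤ e_tol, and returns the lowest feasible bound's estimate
once the interval is resolved to λ_tol.

**Choice of the norm ball.**  Two unitarily invariant constraints fit this
scheme: the spectral-norm ball (projection: clip singular values at λ) and
the nuclear-norm ball (projection: soft-threshold singular values so they
sum to λ).  The package defaults to the nuclear ball and this is a
deliberate, load-bearing choice: the zero-filled matrix is itself a
completion whose *spectral* norm is no larger than that of any coherent
completion, so with a spectral ball the bisection terminates at the
zero-fill fixed point and nothing is imputed (we verified this on both
random low-rank matrices and synthetic spectra; hidden-entry errors never
fell below 100%).  With the nuclear ball the smallest feasible λ is the
minimum-nuclear-norm completion — the standard convex relaxation of rank
minimisation — and hidden entries of rank-2 test matrices are recovered to
~0.1% (see the acceptance studies).  The spectral clip remains available
(`constraint="spectral"`, `clip_spectral`) for completeness.

### Refinement

Completing the full matrix ignores which segments actually resemble the
corrupted one.  The refined method (RMC):

1. models every row per band as a normalised Gaussian
   `A/(√(2π)σ)·exp(−(f−f₀)²/(2σ²))` fit to its known bins (area `A` in
   ms², centre `f₀` and width `σ` in Hz);
2. computes the Pearson correlation γ_{j,q} of the modelled target and
   candidate spectra over the target's known bin indices — under an
   HF-band mask the selection is therefore driven by the LF lobe;
3. keeps the `K` highest-correlated rows (ties to the smaller index) and
   stacks them under the target row: a (K+1) × n_fr refined matrix in
   which only the target row has hidden entries;
4. runs the bisection completion on the refined matrix and returns its
   first row, with the observed bins re-imposed exactly.

If no band of the target row can be modelled (e.g. all-zero known bins),
the correlations fall back to the raw known-bin values with a logged
warning.

Estimates are scored with NRMSE = RMSE over the hidden bins divided by the
sample standard deviation (N−1) of the true hidden values; 1.0 therefore
means "no better than predicting the mean".

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `e_tol` | 1e-8 | absolute Frobenius fidelity on observed entries |
| `lambda_tol` | 10 | absolute resolution of the norm-bound bisection |
| `K` | 9 | reference segments in the refined matrix |
| `inner_tol` / `inner_max_iter` | 1e-12 / 2000 | fixed-point stop at one λ |
| LF / HF bands | 0.04–0.15 / 0.15–0.4 Hz | modelling and analysis bands |
| Welch | nperseg 256, Hamming, 50% overlap, nfft 1024 at 4 Hz | Δf = 1/256 Hz |
| band-pass | 0.03–0.9 Hz, order-4 Butterworth, zero phase | tachogram conditioning |
| SQI gate | 0.9 | minimum mean beat-agreement per 5-minute segment |

`e_tol` and `lambda_tol` are **absolute**, so they presuppose a data scale:
with PSDs in ms²/Hz (the conventional HRV unit; LF areas of a few hundred
ms² give matrix nuclear norms of 1e4–1e5) the bisection resolves the
feasibility boundary to a relative precision of ~1e-3 or better.  On
unit-scale data `lambda_tol = 10` would exceed the whole bisection interval
and the completion would be uselessly coarse — scale the data, or scale
`lambda_tol`, accordingly.  All package defaults (generator, examples,
studies) use ms²/Hz.

`K = 9` is the default refined-matrix size; the `sweep_k` utility
recomputes the error-vs-K curve for any matrix (on the README's worked
example the curve plateaus from K ≈ 7 onward, with K = 9 within ~2× of the
sweep minimum).

## Numerical choices

* **Inner stopping.**  The POCS iteration converges linearly with a rate
  approaching 1 near the feasibility boundary.  The inner loop stops when
  ε changes by less than `inner_tol = 1e-12` (or immediately once
  ε ≤ e_tol/2), with a 2000-iteration cap; looser settings (1e-10 / 500)
  misclassify near-boundary bounds as infeasible and push the final λ
  ~20% above the boundary, visibly degrading the fill.
* **Warm start.**  Successive bisection bounds start T from the previous
  estimate rather than the zero fill.  The limit point of POCS is a point
  of the (convex) intersection regardless of the start, and warm starting
  cuts the iteration count several-fold.
* **Exit rule.**  The driver exits once the λ-interval is resolved to
  `lambda_tol` *and* some feasible bound has been seen, returning the
  lowest feasible bound's estimate even if the final midpoint was
  infeasible.  This keeps the outer iteration count within
  ceil(log₂(‖S‖_*/λ_tol)) + 1 (asserted in the tests); insisting that the
  final midpoint itself be feasible can burn extra iterations near the
  boundary for no change in the returned estimate beyond the λ_tol
  resolution.
* **Initialisation of hidden entries**: zero, consistent with starting
  from A_Ω(S).
* **Gaussian fits** use bounded trust-region least squares with a
  deterministic start (centre at the band argmax, area at the trapezoidal
  band power, width at a sixth of the band width) and bounds that keep the
  centre inside the band and the width between one grid step and the band
  width; fits are therefore reproducible bit-for-bit.
* **Degenerate inputs**: all-hidden masks, zero-variance correlation
  vectors, zero band power and sub-5-point bands raise typed errors rather
  than returning silently wrong numbers; the SVT baseline raises after a
  10× residual growth over 50 iterations.

## The synthetic generator

`synth_tachogram` produces RR series `rr_i = mean_rr + a_LF sin(2π·0.1 t)
+ a_HF sin(2π·0.25 t) + ε` with a 0.2 s physiological floor — the minimal
signal that puts energy at controlled LF/HF positions.  It deliberately
omits ectopy, non-stationarity and detector noise, so pipeline tests
exercise geometry (peak positions, band powers), not robustness to
arrhythmia.

`synth_spectrum_matrix` draws `n_prototypes` (default 3) prototype spectra
— one LF Gaussian (area 300–800 ms², centre 0.08–0.12 Hz) plus one HF
Gaussian (area 150–500 ms², centre 0.2–0.3 Hz) — and mixes them per row
with Dirichlet(1) weights (or near-pure cluster weights for selection
tests), adding N(0, 10 ms²/Hz) measurement noise and clipping at zero.
Defaults: 60 rows, matching a typical hour-long recording's worth of
5-minute segments.  Rows of real spectrum matrices are *serially*
correlated (neighbouring segments resemble each other), which the
exchangeable mixture does not emulate; passing tests therefore demonstrate
the low-rank mechanism, not temporal-neighbour effects, and the
benchmark's SVT-baseline errors are pessimistic relative to recordings
with strong serial structure.

## Evaluation studies

`hrvmc.evaluation` fixes three desk-scale studies used by the tests and
`scripts/acceptance.py`: (i) recovery of random rank-2 30×40 matrices
(factors N(0,10), 30% hidden) with the success rate at 1e-2 relative
error; (ii) agreement with a brute-force nuclear-norm grid search on 3×3
rank-1 matrices with one hidden entry; (iii) the masking benchmark on the
default synthetic ensemble (fresh matrix per seed, random target row,
HF-centred contiguous mask at 30%/70%, RMC with K=9 vs SVT).  The masking
study uses 40 seeds: the per-seed NRMSE distribution is heavy-tailed and
mean-based comparisons need the larger sample to be stable; medians are
stable already at 20.

## Known limitations

* The completion assumes the hidden region of the target row is linearly
  predictable from correlated rows; a segment unlike every other segment
  (novel physiology confined to the hidden band) cannot be recovered, and
  the NRMSE against held-out truth is the guard.
* Band-shaped masks wider than the HF band spill into LF and remove the
  reference information the selection relies on; errors grow accordingly.
* One target row is processed at a time; other corrupted rows contribute
  their observed values only.
* The SQI is an agreement fraction between two detectors' annotations, a
  documented stand-in for detector-specific quality indices.
* Absolute tolerances tie the method to the ms²/Hz scale (see above).
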