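# hrvmc

Estimation of uncertainty-affected regions of heart-rate-variability (HRV)
power spectra by low-rank matrix completion.

Frequency-domain HRV analysis summarises autonomic cardiac regulation
through the power spectral density (PSD) of the RR-interval tachogram: the
low-frequency band (LF, 0.04–0.15 Hz, Mayer-wave/baroreflex activity) and
the high-frequency band (HF, 0.15–0.4 Hz, respiratory sinus arrhythmia).
Motion artefacts, missed beats and interpolation distort parts of the
spectrum — often concentrated in one band — and bias LF/HF metrics.  When a
recording is cut into 5-minute segments and the per-segment PSDs are stacked
into a matrix `S ∈ R^{n_r × n_fr}`, the rows are strongly redundant and `S`
is approximately low rank, so corrupted bins can be treated as *missing
entries* and re-estimated by matrix completion.

## Method

For a segment `s_j` with hidden bins, the package solves the interest-zone
approximation

```
min ‖A_Ω(X) − A_Ω(S)‖_F   s.t.   p(X) ≤ 0,    p(X) = ‖X‖ − λ,
```

where `A_Ω` restricts to the observed entries and `‖·‖` is a unitarily
invariant norm bound (the nuclear-norm ball by default — the convex
surrogate for rank; a spectral-norm variant is provided for completeness).
At a fixed `λ` the problem is solved by alternating a projection onto the
norm ball with restoration of the observed entries; an outer bisection on
`λ ∈ [0, ‖A_Ω(S)‖_*]` finds the smallest bound at which the observed
entries can still be matched to the fidelity tolerance `e_tol = 1e-8`,
resolving the interval to `λ_tol = 10`.

The **refined** completion (RMC) shrinks the problem before completing:
each segment's spectrum is modelled per band as a normalised Gaussian
`A/(√(2π)σ)·exp(−(f−f₀)²/2σ²)`; segments are ranked by the Pearson
correlation of the modelled spectra over the target's *known* bins (for an
HF-band mask the LF lobe drives the ranking); and only the `K` (default 9)
best-correlated rows are stacked with the target into a small refined
matrix that is completed instead of `S`.  A classic singular value
thresholding (SVT) completion of the full matrix is included as the
baseline, and estimates are scored by the NRMSE over the hidden bins
(RMSE divided by the sample standard deviation of the true hidden values).

The full pipeline from raw RR intervals is included: outlier flagging and
interpolation, beat-level signal-quality gating from two QRS detectors'
annotations (segments kept when mean SQI > 0.9), 4 Hz cubic resampling, a
zero-phase 0.03–0.9 Hz Butterworth band-pass, and Welch PSDs (50% overlap)
stacked into the spectrum matrix.  A seeded synthetic generator produces
sinusoidally modulated tachograms and mixture-of-prototypes spectrum
matrices so everything is testable without clinical data.

## Worked example

```python
import numpy as np
from hrvmc import (SynthMatrixParams, synth_spectrum_matrix, FULL_BAND,
                   MaskSpec, apply_mask, rmc_estimate, svt_complete, nrmse)

matrix, _ = synth_spectrum_matrix(SynthMatrixParams(seed=42))  # 60 segments
S = matrix.restrict(FULL_BAND)                                 # 0.04-0.4 Hz, 92 bins
mask = apply_mask(S, MaskSpec(target_row=5, ratio=0.3))        # hide 30% of row 5 (HF)

estimate, result, selection = rmc_estimate(S, mask, j=5, k=9)
print("RMC NRMSE:", round(nrmse(estimate, S.rows[5], mask.hidden[5]), 3))
print("SVT NRMSE:", round(nrmse(svt_complete(S.rows, mask)[5],
                                S.rows[5], mask.hidden[5]), 3))
print("selected segments:", selection.selected)
```

prints

```
RMC NRMSE: 0.013
SVT NRMSE: 1.7
selected segments: [54, 6, 31, 32, 46, 23, 14, 3, 52]
```

i.e. the refined completion reconstructs the hidden HF bins to about 1% of
their natural variability, two orders of magnitude better than the SVT
baseline, using nine reference segments whose modelled LF spectra correlate
best with the target's.

The same is available from the shell (`hrvmc simulate`, `hrvmc preprocess`,
`hrvmc psd`, `hrvmc estimate`, `hrvmc evaluate`); see `hrvmc --help`.

There is also a scikit-learn surface: `IZMAImputer`, `SVTImputer` and
`RefinedMCImputer` are transformers that treat NaN entries as missing, so
they compose with sklearn pipelines and `clone`/`get_params`.

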