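# Methods and numerical choices

This document records the model conventions, estimator designs and known
limitations behind `texelec`. The package is organized around a synthetic
measurement bench whose defaults mirror the study conditions it emulates:
a 5 V peak-to-peak source, a 1 kΩ reference resistor, frequency sweeps
from 0.1 Hz to 10 kHz, 10 samples/s polarization series, and 1 kHz
two-channel ECG.

## Contact-impedance measurement model

The measurement circuit is a single series loop: source `V_g`, reference
resistor `R_ref`, two identical electrode contacts `Z_contact`, and the
body segment between the electrodes `Z_body` (default: purely resistive
1 kΩ). The loop current is `I = V_g / (R_ref + 2·Z_contact + Z_body)`.

Two probe configurations are simulated:

* **Configuration A** probes the voltage at the second electrode,
  `V_e2 = V_r + I·(Z_contact + Z_body)`, so
  `V_21 = V_e2 − V_r` gives `Z_sum = Z_contact + Z_body = V_21 / I`.
* **Configuration B** probes the source itself, `V_21 = V_g − V_r`,
  giving `Z_12 = 2·Z_contact + Z_body`.

With `I = V_r / R_ref` in both cases, the decomposition is pure
arithmetic: `Z_contact = Z_12 − Z_sum` and `Z_body = 2·Z_sum − Z_12`.
Ground-truth phasors attached by the simulator satisfy these equations to
machine precision by construction. A negative real part in the recovered
`Z_contact` is physically impossible and sets a warning flag rather than
being silently discarded.

All three contacts are assumed identical within a measurement; the
subtraction algebra implicitly requires this.

**Sampling-rate policy.** Sweep records use `fs = clip(50·f, 1 kHz,
1 MHz)` and 10 cycles per frequency; frequencies that would yield fewer
than 20 samples per cycle are rejected by the simulator. At the top of the
band this leaves 50 samples per cycle, which bounds the raw
cross-correlation lag resolution at 7.2°; sub-lag refinement (below)
reduces the actual error well under that.

## Phasor extraction

**DC removal.** The high-pass specified for this protocol (cut-off
0.05 Hz, order 2000) cannot be realized as a windowed-sinc high-pass: at
1 kHz sampling, 2001 taps cannot place a transition at 5·10⁻⁵ of the
Nyquist frequency, and the resulting kernel has no usable DC rejection.
Instead `remove_dc` uses a DC-blocker kernel — a unit impulse minus a
normalized Hann window of the same length — which subtracts a windowed
running mean. This has an exact zero at DC, |H| ≈ 2.6·10⁻⁴ at 0.01 Hz
(≈ −72 dB), and passband flatness |H−1| ≈ 1.7·10⁻⁴ at 1 Hz
(fs = 1 kHz, order 2000). The Hann window is chosen over Hamming or
Chebyshev because its sidelobes decay as 1/f³, which keeps the filter
idempotent to better than 10⁻⁶ in the passband; windows with flat sidelobe
pedestals fail that, and windows with narrower sidelobes have mainlobes
too wide to pass 1 Hz within 1%. For records shorter than the nominal
order the order is reduced to a third of the record length with a logged
warning, and half a kernel length is trimmed from each end after
filtering.

**Amplitude.** `amplitude_peaks` locates cycle maxima and minima
(prominence-gated at 10% of the span), refines each by parabolic
interpolation, and returns half the distance between the mean maximum and
mean minimum. Using the max–min midpoint rather than the sample mean makes
both the amplitude and the derived DC-center estimate immune to records
holding a non-integer number of cycles — the raw mean of a sinusoid
observed over `n` cycles is biased by up to `A/(π·n)`, which at the bench's
~7 usable cycles would be a 4–5% error, enough to corrupt arcsin-based
phase estimates by several degrees.

**Phase, Lissajous method.** `θ = arcsin(y0/Y0)`, with `y0` read at every
positive-going zero crossing of the reference (linearly interpolated,
averaged) and `Y0` from `amplitude_peaks`. The arcsin branch confines the
result to [−90°, 90°]; `waveform_to_phasor` disambiguates obtuse phases by
the sign of the zero-lag cross-correlation.

**Phase, cross-correlation method.** `θ = 360·l·f/fs` where `l` maximizes
`r_xy(l)`. Two refinements over the textbook formula:

* *Full-overlap correlation.* The reference is trimmed by half a period
  (plus one sample) on each side and correlated in valid mode, so every
  candidate lag sums over the same window. Full-mode correlation has a
  triangular envelope that biases the peak toward zero lag by up to a
  degree on short records.
* *Cosine-fit interpolation.* The correlation of two same-frequency
  sinusoids is a cosine in the lag, so a three-point fit
  `frac = −atan2(s, r(l))/ω` with `s = (r(l−1) − r(l+1))/(2 sin ω)`
  recovers the peak position exactly for clean signals. Without it the
  resolution is one lag step (3.6° at 100 samples per cycle), which would
  not meet the 1° phase-agreement requirement. `refine=False` restores the
  literal integer-lag estimator.

Ties among equal correlation maxima resolve to the smallest |l|; results
wrap to (−180°, 180°].

## Cole model

`Z(ω) = R∞ + Σ_k R_k/(1 + R_k·C_k·(jω)^{α_k})`, principal branch of the
complex power, with the analytic limit `R∞ + Σ R_k` at f = 0. The
single-dispersion form nests a parallel RC at α = 1.

`ColeModel.fit` minimizes residuals of `log10|Z|` (magnitude mode) or
stacked real/imaginary parts (complex mode) with `scipy.optimize.
least_squares` (trust-region reflective). R∞, R_k and C_k are optimized in
log10 space — they span 5+ orders of magnitude — with α bounded in (0, 1].
Initialization is a plateau heuristic: R∞ from the high-frequency
magnitude floor, R_1 from the low-frequency plateau minus R∞, α = 0.8, and
C from the geometric-mid-band corner condition `ωRC = 1`. Standard errors
come from the delta method on the pseudo-inverse of `JᵀJ` at the solution.
Fitting needs ≥ 5 frequencies spanning ≥ 2 decades (≥ 8 and 3 decades for
two dispersions); non-convergence is reported in the result object, not
raised.

## Polarization statistics

* `exchange_ratio`: mean absolute first difference, reported in µV per
  sampling interval (0.1 s at 10 samples/s). For i.i.d. Gaussian samples
  with standard deviation σ its expectation is `2σ/√π`, which the test
  suite uses as a closed-form oracle.
* `group_exchange_ratio`: unweighted mean of per-series ratios.
* `mean_polarization`: mean absolute DC potential in mV, optionally after
  outlier screening.
* `iqr_filter`: Tukey fences at `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`, quartiles
  by linear interpolation. The fences are re-evaluated on the retained
  values until a fixed point, making the filter idempotent; a single pass
  is not (removing a gross outlier can shrink the quartile range enough to
  expose another point), and one pass is what it almost always takes.

## ECG quality and segmentation

**Filter bank.** Kaiser-window (β = 0.5) FIR stages of order 150:
bandstops 55–65 Hz and 115–125 Hz, bandpass 0.05–150 Hz. The stated order
is far too short to realize the 0.05 Hz high-pass edge at 1 kHz sampling,
so the bank exports its measured frequency response rather than a nominal
one; the measured response is also what the test oracles use. Stages are
applied by 'same'-mode overlap-add convolution, which compensates the
linear-phase group delay so annotations stay aligned. The full design
needs `fs > 300`; between 150 and 300 Hz the 120 Hz stopband is omitted
with a warning once its upper edge no longer fits below Nyquist with a 5%
margin, and the bandpass edge is clipped; below 150 Hz design fails.

**Noise power.** `mean(|original − filtered|²)` in mV². For an injected
60 Hz tone of amplitude `a` the removed-component power is
`a²/2 · |1 − H(60 Hz)|²` with `H` the delay-compensated cascade response —
verified within 5% in the acceptance suite.

**Segmentation.** QRS detection is Pan–Tompkins (5–15 Hz bandpass,
derivative, squaring, 150 ms moving-window integration, adaptive dual
thresholds with search-back, 200 ms refractory), with R refined to the
largest absolute bandpassed deflection within 75 ms. Delineation finds Q
and S as opposite-polarity extrema within 80 ms of R, and P and T as
smoothed (12 Hz low-passed) maxima in [−300, −50] ms before Q and
[+80, +450] ms after S, subject to an amplitude floor of 5% of the R
amplitude above the local baseline. A beat is complete when all five
fiducials are present; edge-truncated beats are incomplete, not errors.
The error rate is `100·(1 − N_complete_test/N_complete_ref)`, clipped to
[0, 100], undefined (raised) when the reference has no complete beats.

## Statistics

Group comparisons follow a fixed decision tree (a pure function, see
`select_test`): assumptions are screened at α = 0.05 — normality of pooled
within-group residuals by Shapiro–Wilk (n < 50) or Kolmogorov–Smirnov, and
homoscedasticity by Levene — then a parametric test (one-way ANOVA, paired
t, or repeated-measures ANOVA) or its nonparametric counterpart
(Kruskal–Wallis, Wilcoxon rank-sum or signed-rank) is dispatched. No
multiple-testing correction is applied by default; `holm_adjust` is
available. Empirical type-I error of every branch is held between 1% and
10% at α = 0.05 in the acceptance suite.

Sheet conductivity is `σ = 1/(R_s·t)` converted to S/cm. Note that the
product `R_s·t` itself is a resistivity (Ω·m); only its inverse carries
conductivity units.

## Synthetic generators: realism and limits

* **ECG**: sum-of-Gaussians PQRST templates (fixed offsets/widths,
  configurable amplitudes) on a strictly periodic beat train, plus shared
  powerline and baseline-wander components and per-channel white noise.
  There is no heart-rate variability, no respiration coupling, no realistic
  muscle-artifact spectrum, and wave corruption is all-or-nothing
  suppression of whole waves on the test channel (exactly
  `round(fraction · n_beats)` beats, seeded). Adequate for validating
  detectors and error-rate bookkeeping; not a physiological simulator.
* **Impedance bench**: noise-free by default (a Gaussian noise option
  exists); source, resistor and contacts are ideal and identical; no
  amplifier loading, cable capacitance or drift.
* **Polarization**: DC offset + linear drift + optional step artifacts +
  white noise; real electrode drift is neither linear nor stationary.

## Limitations

* Generator defaults represent one specific measurement protocol; the
  statistics of real recordings (electrode-dependent noise spectra,
  motion) are out of scope.
* The Cole fit reports delta-method standard errors, which are meaningful
  only near a well-conditioned optimum; for noise-free self-recovery they
  are numerically tiny and should not be over-interpreted.
* The delineator is a windowed heuristic tuned to the synthetic morphology;
  on real ECG it is a reasonable baseline, not a validated clinical
  algorithm.
* Phase estimators assume a single dominant sinusoid at a known frequency;
  harmonics or broadband noise degrade both methods, the Lissajous
  intercept first.
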