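# Methods

This note documents the models, the numerical choices and the limits of the
package: what the synthetic-data generator emulates, how each extraction
stage is defined, and what passing the test suite does and does not show
about real recordings.

## Protocol geometry

One contraction covers 90° of knee excursion at a dynamometer-enforced
240 °·s⁻¹, giving a duration of 90/240 = 0.375 s. The protocol is
`n_sets = 20` sets of `reps_per_set = 8` contractions (160 total per
subject), sets starting every 30 s. Torque and angular velocity are sampled
at 100 Hz, surface EMG at 2048 Hz. All intervals in the pipeline are
half-open `[start, end)` in seconds, with t = 0 at the start of each file.

## Fatigue model (ground truth)

Fatigue is programmed as per-metric multiplicative **decline schedules**:
the fraction of the subject's baseline remaining at set *s*, linear in set
index from 1.0 at set 1 to a configured end fraction at set 20. Block means
of such protocols decline roughly linearly and no within-set functional
form is established, so within-set decline defaults to flat (exposed as
`within_set_decline`). Default end fractions (fraction remaining):

| metric | end fraction | per-subject change |
|---|---|---|
| RTD | 0.549 | −45.1 % |
| T_mean | 0.686 | −31.4 % |
| T_peak | 0.777 | −22.3 % |
| RER | 0.789 | −21.1 % |
| EMG envelope scale | 0.968 | −3.2 % |
| early-window spectral center | 0.80 | ≈ −20 % |

Pre→post fractions for the neuromuscular tests: IMVC 0.674, evoked peak
torque 0.757, evoked RTD 0.753, 10:100 Hz doublet ratio 0.732, M-wave 1.0
(no change), voluntary activation 96.4 % → 92.3 % (absolute). Because every
subject shares the schedule, the per-subject percent change *is* the
programmed value, and the group mean of per-subject changes recovers it
without aggregation bias.

Between-subject variability is log-normal with a common "strength" factor
(SD 0.15 of log) scaling all torque quantities, a common EMG amplitude
factor (SD 0.25) scaling M-wave, envelope and RER together (they share the
electrode/tissue pathway), and small independent shape jitters (3–5 %) on
ratios such as RTD/T_peak. Coupling the baselines this way keeps every
drawn parameter combination inside the region where a monotone torque rise
with the programmed slope, peak and mean exists.

## Signal models

### Torque

A contraction's noise-free torque is piecewise: zero baseline (0.5 s), a
**linear rise with slope exactly equal to the programmed RTD** (default
115 ms), a cubic Hermite knee (entry slope = RTD, exit slope 0) reaching
the programmed peak at 160 ms — the time-to-peak is held constant through
fatigue, matching observation — and a smoothstep tail whose end level is
solved **in the discrete sample domain** so the sample mean over the
contraction window equals the programmed T_mean exactly (when the required
end level would be negative, the tail instead reaches zero at a solved
earlier time). For steep RTD relative to the peak, the linear phase
shrinks (never below the 75-ms slope window) and the peak time moves
earlier, snapped to the sample grid so one sample lies exactly on the peak.

Consequences: the 0–75 ms OLS slope equals the programmed RTD *exactly*
even when onset detection is tens of milliseconds late; the peak sample
equals the programmed T_peak; the window mean equals the programmed
T_mean. Measurement noise is additive white Gaussian with SD
`noise_levels["torque"] = 0.05` × the contraction's peak torque (making it
multiplicative across fatigue, as tremor roughly is, so max-operator biases
cancel in percent changes).

The velocity trace ramps to a plateau 5 % above the nominal target
(dynamometers overshoot; the margin keeps plateau noise from crossing the
target), crossing the target at 57 ms, and releases steeply after the
programmed duration so the first sample past it is already below target —
the detected isokinetic end is then exactly onset + duration.

### EMG

Raw EMG is a band-limited Gaussian carrier times a deterministic envelope,
plus a white measurement floor (1 % of the envelope scale). The carrier is
produced by an effectively time-varying 4th-order Butterworth band-pass
(proportional bandwidth 0.6 × center frequency), realized as overlap-added
62.5-ms Hann-windowed blocks each filtered at the programmed center
frequency for its time — a per-sample time-varying IIR would need
coefficient interpolation with no stability guarantee, while windowed
blocks are exact for piecewise-constant trajectories and COLA-consistent.
The carrier is then normalized to unit RMS *locally*, at the 50-ms scale of
the downstream RMS analysis window: the programmed envelope is the
generator's ground truth, so it must equal the local RMS of the signal.
(A global normalization would couple the envelope to the time-varying band
gain; the price of the local one is that the amplitude-fluctuation
statistics of real EMG are not emulated — only its spectral content and
envelope.)

The envelope rises linearly at the programmed RER for 100 ms, Hermite-knees
to the programmed scale at 228 ms, and decays to 0.75 × scale by the end of
the contraction. EMG_mean is therefore *not* an independent dial: its truth
value is the analytic mean of this envelope and is recorded per contraction
in the ground truth. Spectral compression is programmed as a trajectory:
the band center is `c0 × factor` for the first 190 ms of the contraction,
recovering linearly to `c0` by 215 ms — i.e. fatigue alters only the early
contraction, which is what the binned if_mean comparison must detect.

### Evoked responses

Twitches and doublets are bi-exponential,
`K (e^{−t/τ_d} − e^{−t/τ_r})` with K normalizing the continuous maximum to
the programmed amplitude. The rise constant is solved (Brent) so the true
derivative maximum equals the programmed evoked RTD; since that maximum is
bounded below by e·amplitude/τ_d, the decay constant lengthens beyond its
0.1 s default when a subject's programmed evoked RTD sits near the bound.
The M-wave is a Gabor-like biphasic pulse rescaled to an exact programmed
peak-to-peak amplitude. IMVC traces rise smoothly to a plateau with a
superimposed doublet added at the stimulation time.

## Extraction: numerical choices

- **Onset detection** — earliest sample exceeding baseline mean + 3 SD and
  staying above for 30 ms (torque) / 20 ms (EMG RMS), then (torque only) a
  double-threshold backtrack to the sample after the last one below
  baseline + 1 SD. Backtracking removes most of the rise-speed-dependent
  detection delay; it is disabled on RMS envelopes, whose near-zero
  baseline SD would make the low threshold erratic. A sample exactly at the
  low threshold is treated as the last baseline sample (exact for
  noise-free signals).
- **RTD / RER** — OLS slope over all samples in `[onset, onset + 75 ms]`
  (8 samples at 100 Hz, ~154 at 2048 Hz). OLS equals the endpoint slope on
  linear data and is less noise-sensitive; "average slope" admits both
  readings.
- **T_peak / T_mean window** — movement onset (detected on the velocity
  trace, whose rise does not change with fatigue) to the isokinetic phase
  end (first sample back below the target velocity). Anchoring this window
  to velocity rather than torque removes a fatigue-asymmetric truncation
  bias in T_mean of ≈1 percentage point.
- **Zero-phase filtering** (`sosfiltfilt`) everywhere a band-pass is
  applied, so onset timing is not lag-shifted; the effective magnitude
  response is the squared design response.
- **RMS** — centered 50-ms rectangular window, truncated at the edges. The
  centered window smears the activation onset symmetrically and looks
  ~25 ms ahead, which is why the detected EMG onset precedes the true one;
  the induced multiplicative bias on RER cancels in normalized ratios.
- **Evoked RTD** — maximum of the central-difference derivative. At 100 Hz
  this underestimates the true derivative maximum of fast twitches by a
  shape-dependent factor; the factor is common to pre and post (amplitude
  and evoked RTD decline almost equally), so the percent change survives.
- **CWT** — Torrence–Compo frequency-domain algorithm, zero-padding to the
  next power of two, Morlet ω₀ = 6, wavelet scale from center frequency via
  λ = 4π·s/(ω₀ + √(2+ω₀²)). Samples inside the cone of influence (e-folding
  time √2·s) are excluded from bin means by default (`exclude_coi`) —
  edge artifacts would otherwise dominate the earliest bin of short traces.
- **Stepwise regression** — forward entry by R² gain, partial-F p < 0.05,
  with a collinearity guard (|r| > 0.9 against an included predictor).
- **RM ANOVA** — textbook within-subject decomposition,
  F = MS_cond/MS_(cond×subject); no sphericity correction by default (the
  cross-check against `statsmodels.AnovaRM` lives in the test suite). Tukey
  HSD uses the studentized-range distribution on the *RM* error term; an
  independent-groups Tukey (pooled between-group MS) would be wrong here.
- **VO₂ kinetics** — τ initialized by grid search (the remaining parameters
  are linear and solved in closed form per candidate τ), refined by
  `curve_fit`; constant series return their mean with
  `tau_identifiable=False`.

## What the tests show — and do not

Noise-free generated torque is recovered to machine precision through the
full detection + extraction chain, and all programmed group-mean changes
are recovered from noisy signals at the study size (11 subjects) within
twice the Monte-Carlo standard error. This validates the *pipeline*, not
the realism of the generator: real surface EMG has motor-unit structure,
nonstationary recruitment, electrode artifacts and antagonist activity that
white-noise carriers do not emulate; real torque onsets are not preceded by
perfectly flat baselines; dynamometer velocity control is less clean than
the simulated plateau. Estimator properties that depend only on
second-order signal statistics (slopes, means, band powers, centroids)
transfer; anything sensitive to EMG fine structure does not.

Known quantitative limitations:

- **Spectral quantization of if_mean.** With 11 log-spaced centers and a
  Morlet mother, the intensity-weighted centroid of a *narrowband* signal
  quantizes toward the nearest center frequency (a mid-gap 80 Hz tone reads
  ≈90 Hz). The original asymmetric filter shapes for which this spacing was
  optimized balance neighboring bands much better. Broadband EMG is barely
  affected (programmed 100 Hz centroids recover to ~1 %), and the pre/post
  bin comparison cancels the residual bias — but absolute if_mean values of
  narrowband signals should not be over-interpreted.
- **EMG_peak overshoot.** The maximum of a fluctuating 50-ms RMS envelope
  overshoots the programmed envelope scale by ≈25–30 %; the overshoot is
  multiplicative and cancels in all normalized quantities.
- **Voluntary activation.** The superimposed twitch of a well-activated
  muscle (a few N·m on a 300 N·m plateau) is comparable to the noise of the
  max-over-window extractor, so VA estimates are biased a few percentage
  points low and noisy. VA is reported but should be read qualitatively.
- **EMG_mean decline** is a consequence of the envelope shape and the
  programmed scale/RER declines, not an independently programmed target.

## Problem sizes

The test suite simulates the full study (11 × 20 × 8 contractions with EMG
at 2048 Hz) once as a shared fixture (~20 s) plus small purpose-built
protocols per module; Monte-Carlo checks use 300–500 replicates where an
expectation is asserted. `scripts/acceptance.py` runs one full simulation
and completes in well under a minute.
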