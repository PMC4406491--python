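# neurofatigue

Simulation and analysis of **repeated maximal isokinetic contraction
fatigue protocols** for the knee extensors: 20 sets of 8 maximal knee
extensions at 240 °·s⁻¹ (≈375 ms each, from a 90° range of motion),
bracketed by pre/post neuromuscular testing with femoral-nerve stimulation.

The package is aimed at neuromuscular physiologists and biomechanists who
need a tested, reproducible implementation of the full computational chain
of such a study — and a synthetic-data generator with exact programmed
ground truth to validate every stage of it.

## What it computes

**Mechanical variables** (torque/velocity at 100 Hz, per contraction):

- *RTD* — rate of torque development, the least-squares slope of the
  torque–time curve over 0–75 ms from contraction onset (N·m·s⁻¹);
- *T_peak*, *T_mean* — peak and mean torque over the isokinetic phase;
- time to the 240 °·s⁻¹ target velocity and time to peak torque.

**EMG variables** (vastus-lateralis surface EMG at 2048 Hz): Butterworth
band-pass 10–500 Hz (zero phase), 50-ms moving RMS envelope, then
*EMG_mean*, *EMG_peak* and the rate of EMG rise
*RER* (0–75 ms slope of the RMS envelope), with two normalizations —
per-subject protocol maximum, and the M-wave amplitude *M_max*
(nEMG_mean, nEMG_peak, nRER).

**Time–frequency analysis**: a Morlet wavelet bank with polynomially spaced
center frequencies

```
F_j = (1/scale) · (j + q)^r ,   scale = 0.3, q = 1.45, r = 1.959, j = 0…10
```

(≈6.9–395 Hz), a Torrence–Compo frequency-domain CWT, per-wavelet intensity
p_j(t) = |W_j(t)|², and the instantaneous mean frequency — a time-resolved
spectral centroid —

```
if_mean(t) = Σ_j F_j p_j(t) / Σ_j p_j(t)
```

averaged over consecutive 75-ms bins of the contraction (0–75 … 300–375 ms).

**Neuromuscular testing**: IMVC (500-ms pre-stimulus maximum), voluntary
activation by twitch interpolation `VA% = (1 − superimposed/resting) × 100`,
evoked peak torque and evoked RTD of potentiated 100 Hz doublets, the
10:100 Hz doublet ratio (low-frequency fatigue index), M-wave peak-to-peak.

**Statistics**: block averaging (four-set blocks / five 20 % intervals as %
of protocol maximum), per-subject percent changes, standardized-β OLS and
forward stepwise regression, one-way repeated-measures ANOVA with Tukey HSD
on the within-subject error term, mono-exponential VO₂ kinetics
`y(t) = y0 + (A − y0)(1 − e^(−t/τ))`, and blood-lactate accumulation.

The synthetic generator programs per-metric multiplicative decline schedules
(set 1 → set 20) and pre→post changes as exact ground truth, so the pipeline
can be validated as a parameter-recovery experiment. See
[docs/methods.md](docs/methods.md) for the signal models and their limits.

## Worked example

```python
import neurofatigue as nf
from neurofatigue.pipeline_cli import analyze_experiment, summarize_analysis

cfg = nf.ProtocolConfig(n_subjects=4, seed=42)      # 4 × 20 × 8 contractions
exp = nf.generate_protocol(cfg)                     # signals + tests + truth
res = analyze_experiment(exp)                       # full extraction chain
summary = summarize_analysis(res, cfg, exp.vo2, exp.lactate)

pc = summary["percent_changes"]
for key in ("rtd", "t_peak", "t_mean", "n_rer", "e_tpeak", "imvc"):
    e = pc[key]
    print(f"{key:8s} {e['mean']:+6.1f} +/- {e['sd']:4.1f} %")
bins = summary["ifmean_bins"]
print("if_mean set 1 :", {k: round(v) for k, v in sorted(bins[1].items())})
print("if_mean set 20:", {k: round(v) for k, v in sorted(bins[20].items())})
```

prints

```
rtd       -43.9 +/-  5.1 %
t_peak    -22.2 +/-  0.3 %
t_mean    -31.7 +/-  0.6 %
n_rer     -25.7 +/-  7.7 %
e_tpeak   -24.8 +/-  0.7 %
imvc      -32.7 +/-  0.2 %
if_mean set 1 : {'0-75': 108, '150-225': 109, '225-300': 109, '300-375': 108, '75-150': 108}
if_mean set 20: {'0-75': 86, '150-225': 88, '225-300': 106, '300-375': 108, '75-150': 91}
```

Each line is the group-mean ± SD per-subject percent change (set 1 vs set
20, or pre vs post) recovered by the pipeline from noisy simulated signals;
the generator had programmed −45.1 % (RTD), −22.3 % (T_peak), −31.4 %
(T_mean), −21.1 % (nRER), −24.3 % (evoked peak torque) and −32.6 % (IMVC).
The if_mean rows show the fatigue-induced spectral compression confined to
the first ~225 ms of the contraction. With only 4 subjects the noisier EMG
estimates (nRER) scatter visibly; at the study size (11 subjects) they
recover the programmed values within twice their standard error.

The same workflow is available from the shell:

```bash
neurofatigue simulate -c config.yaml -o data/
neurofatigue analyze  -i data/ -o results/
neurofatigue report   -i results/
```

`config.yaml` holds any `ProtocolConfig` field (`n_subjects`, `seed`,
decline schedules, noise levels, …); all outputs are plain CSV/JSON plus a
run manifest with a config hash for provenance.

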