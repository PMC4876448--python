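# Methods

## The airway model

The upper airway between the snore source (soft palate / pharyngeal wall)
and the neck-surface microphone is treated as one lumped segment of a
collapsible tube.  In the electrical analogy, pressure is voltage and
volume flow is current.  The series branch is `Z_a = R_a + jωL_a` (viscous
resistance and air-column inertance); the shunt branch collects the air
compliance `C_a`, a thermal-loss conductance `G_a`, and a series
R<sub>w</sub>–L<sub>w</sub>–C<sub>w</sub> wall branch for the tissue layer.
The model output is the pressure across the shunt — the voltage-divider
transfer function `H = Z_sh/(Z_a + Z_sh) = 1/(1 + Z_a·Y_sh)`.

A single lumped segment is the simplest topology whose resonance
`1/(2π√(L_aC_a)) = c/(2πl)` depends on airway length only; this matches the
model's intended behavior, where the first resonance is set by length while
area and wall thickness act on the gain, not the resonance.  Multi-segment
transmission lines and nasal/oral branching are out of scope.

### Element forms

Per tube of length `l`, area `A`, lumen perimeter `S = 2πT_r`:

| element | form | physics |
|---|---|---|
| `L_a` | `ρl/A` | air-column mass |
| `C_a` | `Al/(ρc²)` | adiabatic compressibility |
| `R_a` | `8μl/(πT_r⁴)` (+ optional `(S·l/A²)·√(ωρμ/2)`) | Poiseuille; boundary-layer term selectable |
| `G_a` | `κ·S·l·√ω`, `κ = 8.9·10⁻⁹` | wall heat-conduction loss |
| `R_w` | `b/(S·l)`, `b = 1600 N·s/m³` | tissue damping per unit area |
| `L_w` | `ρ_w·h_eff/(S·l)` | tissue mass (see below) |
| `C_w` | `S·l/k`, `k = 3·10⁵ N/m³` | tissue stiffness per unit area |

`κ` lumps `(γ−1)/(ρc²)·√(λ/(2c_pρ))` for humid body-temperature air; `b`
and `k` are in the range reported for yielding vocal-tract walls.

**Wall mass.** The wall inertance uses the *equivalent annulus thickness*
`h_eff = (N_r² − T_r²)/(2T_r)` — the cross-section of the full tissue
annulus between lumen and skin divided by the lumen circumference — rather
than the bare layer thickness `h`.  A radially moving lumen wall must
accelerate the tissue column above it; using only `ρ_w·h` under-weights
that mass by a factor of ~4 at cohort-mean anatomy and lets the wall branch
pull the first resonance up by ~3.5 % at the longest airways.  With the
annulus mass the wall perturbs the resonance by well under 1 %, consistent
with a first resonance that is governed by length alone, while `h_eff`
still grows monotonically as the lumen narrows at fixed neck size (so the
wall keeps its smooth area dependence).  `h_eff` is strictly increasing in
`h` at fixed `T_r`.

### Physical constants

| constant | default | note |
|---|---|---|
| ρ (air) | 1.14 kg/m³ | humid air at 37 °C |
| c | 354 m/s | humid air at 37 °C; sets `c/2πl` = 805 Hz at 7.0 cm |
| μ | 1.86·10⁻⁵ Pa·s | air viscosity |
| ρ_w | 1000 kg/m³ | soft tissue |

All constants live in `PhysicalConstants` and can be overridden from the
TOML run configuration, so alternative property sets drop in without code
changes.

### Resonance location

`|H|` is evaluated on a 1 Hz grid over 100–4000 Hz; the bracketed argmax
(first index on ties) is refined by golden-section search to 0.01 Hz.  The
reported F1 is therefore grid-independent beyond 1 Hz resolution.

### Gain and modeled intensity

The model does not fix an operational "output level", so two quantities
are exposed: the **gain** `20log₁₀|H(f₀)|` at the subject's source pitch
`f₀`, and the **modeled intensity** = gain + Bernoulli source scaling
`−20e·log₁₀(A/A_ref)`.  Narrowing a collapsible tube raises flow speed and
the driving pressure fluctuation; with the dynamic-pressure exponent
`e = 2` (configurable to 1) the source level rises as the fourth power of
the radius reduction.  Any smooth monotone choice of these conventions
yields the same near-perfect negative correlation between percentage area
change and intensity; the conventions are exposed, not hidden.

## Synthesis

`synthesize_snore` implements the source–filter chain: a harmonic source at
the subject's pitch, spectral multiplication by `|H(f)|` (zero-phase; the
acoustic phase does not affect any extracted feature), white microphone
noise at a configurable SNR (default 30 dB), an 8th-order Butterworth 5 kHz
anti-alias low-pass, and peak normalization to −3 dBFS before 16-bit PCM
output at 12.5 kHz.

The default source is a 48-harmonic series with −6 dB/octave rolloff and
3 % cycle-to-cycle period jitter.  A bare sinusoid at ~100 Hz (available
via `n_harmonics=1`) carries no energy near the 450–800 Hz resonance;
harmonic content is what excites it, and jitter — a salient property of
real snoring — spreads the harmonic lines so the narrow resonance is
sampled even when no harmonic lands exactly on it.

The cohort generator samples anatomy from truncated normals at the study
statistics (NC 41.8 ± 2.9 cm, UA-XSA 2.6 ± 0.6 cm², UA-Length 9.1 ± 1.8 cm,
ΔNC +0.5 ± 0.3 cm, ΔUA-XSA −0.4 ± 0.3 cm², pitch 102.1 ± 20.6 Hz on
[50, 300], AHI 27.6 ± 25.8 truncated at 0), resampling draws that violate
`N_r > T_r`.

**What the synthetic data does not emulate:** palatal-flutter source
physics, expiratory snoring, respiratory amplitude envelopes, body/room
acoustics, and any real between-subject variability beyond anatomy and
pitch.  Closed-loop tests therefore show that the analysis stack recovers
what the model injects — they validate the pipeline's internal consistency,
not the model's fidelity to real snorers.

## Feature extraction

* Band-pass 100–4000 Hz: Butterworth of order chosen by `buttord` for
  ≥ 40 dB stop-band at 50/5000 Hz after forward–backward (zero-phase)
  filtering.
* Welch PSD: 100 ms Hamming windows, 50 % overlap, one-sided density.
* Band powers over the eight bands (100–4000 full band, 100–150, 150–450,
  450–600, 600–1200, 1200–1800, 1800–2500, 2500–4000 Hz): average power is
  the *mean* PSD over the band (bandwidth-comparable), dB re 1; relative
  power divides by the full-band mean, so the full band is identically 1.
* Spectral centroid: power-weighted mean frequency in the band (the
  standard definition); an argmax (peak-frequency) variant is selectable
  for sensitivity analysis since both readings of "the frequency containing
  the maximum power" are defensible.
* Pitch: per 25 ms frame, normalized-autocorrelation candidates in
  [50, 300] Hz with parabolic lag interpolation; Viterbi selection with an
  unvoiced state, an octave transition cost, and a small per-octave bias
  against subharmonic candidates (whose autocorrelation ties the true
  period); segment value = median over voiced frames; unvoiced segments
  (e.g. white noise) return missing.  Pitch runs on the *un-band-passed*
  signal: the 100 Hz band edge would attenuate the fundamental itself.
* Formants: 0.97 pre-emphasis, 20 ms Hamming frames at 10 ms hop,
  16th-order autocorrelation LPC via Levinson–Durbin, poles kept when
  bandwidth < 400 Hz and frequency ≥ 150 Hz (raw LPC always produces
  spurious broad and low poles), per-frame F1/F2 median-aggregated.  A
  formant is reported only when stable across frames (IQR ≤ 25 % of the
  median); unfiltered noise scatters its admissible poles over hundreds of
  Hz and correctly reads as missing.
* The snoring-time index is total snore time per sleep stage divided by
  stage time; the energy/hysteresis segmenter (−20/−30 dB re peak frame,
  min 200 ms, merge gap 100 ms) exists to automate synthetic recordings
  only — real studies annotate by listening.

## Agreement statistics

Correlation auto-selects Pearson vs Spearman by a Shapiro–Wilk check at
α = 0.05 on both series (the branch taken is reported); Bland–Altman uses
the sample SD (n−1) and ±1.96 SD limits; paired comparisons auto-select the
paired t-test vs the Wilcoxon *signed-rank* test on the differences — the
signed-rank test is the paired-design intent even where "rank-sum" is the
colloquial name.  A one-way ANOVA helper is provided for across-stage
comparisons; it is reporting convenience, not part of the validated core.

## Reproducibility and problem sizes

All randomness flows from one integer seed, fanned out to stages by a
SHA-256 stage-name hash (`child_seed`), so identical seeds give
bit-identical cohort CSVs and WAV files.  Default study sizes: 12-point
length sweeps, 7-point narrowing sweeps, 50-subject closed-loop cohorts
with 2 s snores at 20 dB SNR — sizes at which every summary statistic in
the test suite is stable to well within its assertion tolerance.

## Known limitations

* Single-segment lumping holds below ~1 kHz for a ~9 cm tube;
  second-resonance (F2) physics needs a transmission line and is not
  modeled — measured F2 appears only as a feature-extraction oracle anchor.
* The exact tissue constants of a given subject are unknown; `b`, `k`,
  `ρ_w` are literature-scale values and the model's F1 is insensitive to
  them by design.
* The Bernoulli source coupling is a level *convention* linking area change
  to intensity; absolute dB values are arbitrary (re 1), only differences
  and correlations are meaningful.
* The resonance is narrow (high Q): measured-F1 recovery leans on source
  jitter and harmonic density, which is also true of real snore recordings
  but is not a validated tissue-damping model.
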