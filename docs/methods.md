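# Methods

This note documents the models, definitions and numerical choices behind
`gawkit`, in the order data flows through the pipeline.

## Synthetic recordings

**Glottal pulse.** One cycle of the unit pulse consists of a closed plateau
at the residual-gap level `gap_rel`, a half-cosine opening ramp to 1, and a
half-cosine closing ramp back to the gap level. `open_quotient` is the open
fraction of the period and `closing_fraction` the closing share of the open
phase; `plateau_frac` positions the pre-opening plateau and must satisfy
`plateau_frac + open_quotient <= 1`. The total closed fraction of the cycle
is `1 - open_quotient`; default configurations keep
`plateau_frac = 1 - open_quotient` so the plateau dial equals the realized
closed fraction. Half-cosine ramps were chosen because every downstream
landmark (closing/opening/plateau durations, gap ratio, mean open area) has
a closed form, which makes recovery tests exact rather than approximate.

**Pulse train.** Per-cycle periods are `round(fs_gaw/f0 * (1 + e))` samples
with `e ~ N(0, jitter_rel)` truncated at ±3σ; per-cycle amplitudes are
`1 + e'` with `e' ~ N(0, shimmer_rel)` truncated likewise. Because periods
are integer samples, the *realized* perturbations differ from the requested
ones; the generator therefore recomputes ground truth (mean period,
std(T)/mean(T), std(A)/mean(A)) from the emitted integer sequence, and all
recovery tests compare against that. Quantization puts a floor of roughly
`0.29 samples / period` on relative jitter — about 0.7% at 100 Hz and 2.2%
at 300 Hz at the 4 kHz frame rate. This floor is a deliberate feature: it
reproduces the sampling-rate artefact by which period-perturbation measures
read out higher at higher fundamental frequencies.

**Left/right split.** `GAW_R` is the unshifted pulse train scaled by
`1/(1+r)` and `GAW_L` the version delayed by `lr_phase_delay_rel` of each
period and scaled by `r/(1+r)`, with `r = lr_amp_ratio`; `GAW_T` is their
sample-wise sum, exactly, including any additive GAW noise (noise is drawn
per half). Positive delay means the right half leads.

**Acoustic model.** The same per-cycle pulse train is evaluated directly on
the 40 kHz grid (not resampled from the 4 kHz track, which would add
interpolation artefacts), first-differenced, and passed through a cascade
of two-pole resonators at 300/2300/3000 Hz (bandwidths 80/150/200 Hz) — a
minimal source–filter model of /i/-like phonation. White noise is added at
`acoustic_snr_db` relative to the filtered signal power. Two warm-up cycles
are prepended and trimmed so the resonator startup transient does not
create a spurious first cycle. Note the resonators impose a group delay of
a few milliseconds, so the acoustic waveform is *not* sample-aligned with
the GAW; the two tracks share cycle timing (F0 agrees within 1%, cycle
counts within ±1), which is what the downstream analysis relies on.

**Cohorts.** Four groups mirror the study design: healthy/disordered ×
female/male, with female f0 sampled from 160–300 Hz and male from
90–160 Hz. Disordered samplers shift jitter (0.01–0.03 vs 0.002–0.008),
shimmer (0.04–0.10 vs 0.01–0.04), residual gap (0.05–0.30 vs 0–0.10),
left/right asymmetry and acoustic noise upward. These disordered levels are
*illustrative* spreads chosen to produce visibly perturbed but analyzable
signals; functional dysphonia is an umbrella diagnosis and no claim of
clinical calibration is made. Recording *i* of a cohort uses the child
random stream `[master_seed, i]`, so cohorts are reproducible element-wise.

## Cycle detection

The dominant period is the argmax of the normalized autocorrelation of the
mean-removed signal over lags corresponding to 80–400 Hz; a peak below 0.2
raises an unvoiced-signal error. Cycles are then delimited at local maxima
(or minima, via negation) found with minimum spacing 0.5× the dominant
period and prominence ≥ 20% of the peak-to-peak range; both thresholds are
module constants chosen conservatively against double-peaked cycles.
Boundaries anchor at the extremum sample itself; cycles are half-open
index intervals `[b_i, b_{i+1})` and partial cycles at the segment edges
are implicitly discarded. GAW_T boundaries are *transferred* unchanged to
GAW_L/GAW_R so all three share one cycle grid.

Maximum-based cycles start between the two halves' delayed peaks, so
measures that compare per-cycle peaks of GAW_L and GAW_R (the phase
asymmetry family) use minimum-based cycles, which contain one complete
pulse each.

## Parameter definitions

Per-cycle table: period `T_i = (b_{i+1}-b_i)/fs`, amplitude
`A_i = max - min` within the cycle (robust to the residual-gap offset),
energy `E_i` = sum of squared mean-removed samples. All standard deviations
are sample (n−1) standard deviations.

| Parameter | Definition |
|---|---|
| F0 [Mean]/[Std] | mean / SD of per-cycle `f_i = 1/T_i` (Hz) |
| MJit | mean absolute adjacent-period difference (ms) |
| Jit(%) | `100 * MJit / mean(T)` |
| PVI | `100 * SD(T)/mean(T)` |
| MShim | mean of &#124;20·log10(A_{i+1}/A_i)&#124; (dB) |
| AVI | SD of `20*log10(A_i/mean(A))` (dB; acoustic only) |
| EPF | `100 * mean|E_{i+1}-E_i| / mean(E)` (GAW only) |
| CQ | closing duration / period |
| SQ | opening / closing duration |
| PQ | closed-plateau duration / period |
| GGI | `A_min/A_max` per cycle (residual-gap ratio) |
| GAI | `(mean - min)/(max - min)` per cycle (normalized mean open area) |
| PhA(I) | (absolute) signed left-right peak delay as a period fraction |
| AmS(I), SpS(I) | signed ratio `(R-L)/(R+L)` and index `min/max` of peak-to-peak amplitudes / cycle-integrated areas |
| WaSI | mean per-cycle Pearson correlation of the two halves |
| CPP | cepstral peak (in 2.5–12.5 ms quefrency) minus trend line fitted over 1–12.5 ms, on the real cepstrum of the dB spectrum of the Hann-windowed segment |
| HNR | `10*log10(N*E(mean waveform) / E(residuals))` after length-normalizing every cycle to the rounded mean cycle length |
| WMC_Max/Mean | max / mean Pearson correlation of adjacent, length-matched cycles |
| NNE | `10*log10(E_interharmonic / E_total)` in the analysis band |
| SNR_K [Mean]/[Std] | per 4-cycle frame: inter-harmonic density extrapolated over the band estimates noise energy; `10*log10((E_total-E_noise)/E_noise)`; mean/SD over frames |
| SNR_Q | mean-waveform vs residual energy over the whole segment, residuals taken after stretching the mean waveform back to each cycle's own length |

PVI, AVI, EPF, GAI and the WMC/Klingholz details follow
coefficient-of-variation / normalized-form conventions; each sits behind
one function so an alternative published variant is a one-function change.

Phase landmarks anchor at the *closed band* (samples within 5% of the cycle
minimum, relative to the cycle range): closing runs from the cycle-start
maximum to the first closed sample, opening from the last closed sample to
the next maximum. Anchoring at the single minimum instead would count a
flat closed plateau as opening time and inflate SQ (a 0.75/0.25
opening/closing pulse would read SQ ≈ 4.7 instead of 3). The 5% threshold
(`plateau_eps`, config-exposed) also means PQ slightly overshoots the true
closed fraction on smooth pulses, because the flat ends of the cosine ramps
dip under the threshold (≈ +0.1 at default settings); PQ remains monotone
in the injected plateau and comparable across recordings analyzed with the
same threshold.

Spectral measures use a Hann window; CPP zero-pads to ≥ 1024; NNE/SNR_K
harmonic bands are `k*f0 ± f0/8` widened to at least 1.5 frequency bins so
an on-bin harmonic's mainlobe stays inside its band; analysis bands are
0–Nyquist for the GAW and 0–5 kHz for the acoustic track. Klingholz frames
are whole cycle groups without zero-padding, which keeps frame harmonics
on-bin. HNR/SNR_Q cap at +60 dB so noise-free synthetic input stays finite.

### Error isolation

`extract_parameters` computes the GAW and acoustic sides independently: a
failure (unvoiced track, too few cycles, degenerate amplitude) fills that
side's entries with NaN and records a flag; nothing is silently dropped.
The 49 column names and their order are frozen
(`ac_*` 14, `gaw_*` non-symmetry 25, `gaw_*` symmetry 10).

## Screening statistics

Per gender (healthy+disordered merged), all 35×14 = 490 GAW×acoustic pairs
are tested. PCC uses the classical two-sided t-approximation. DCC uses the
biased V-statistic estimator (double-centered absolute-difference matrices;
`dcor = sqrt(dCov²/sqrt(dVar_x·dVar_y))`), with p-values from seeded
permutations: `p = (1 + #{perm >= obs})/(1 + n_perm)`, default
`n_perm = 1000`. The permutation set is generated once per gender and
shared across pairs — each pair still sees a valid exchangeable null, and
the screen stays deterministic for a fixed seed. Since the dcor denominator
is permutation-invariant, permuted statistics are compared through dCov².

BY adjustment is applied within each (gender × coefficient-type) family of
490 tests: `adj_(i) = min_{j>=i}(m·c(m)·p_(j)/j)` with `c(m) = Σ 1/k`,
capped at 1. Note a granularity interaction: the smallest permutation
p-value is `1/(n_perm+1)`, and with 490 tests and `n_perm = 200` even the
floor cannot fall below the BY threshold unless hundreds of tests tie
there; DCC relevance calls at small permutation counts are therefore
conservative by construction, and `--n-perm` should be raised (≥ 1000) when
DCC significance, not just magnitude, matters.

Relevance requires both adjusted p < 0.05 and |coefficient| ≥ 0.3; Mukaka
bins: < 0.3 negligible, < 0.5 low, < 0.7 moderate, < 0.9 high, ≥ 0.9 very
high. Missing values are handled by pairwise-complete deletion; `n` is
reported per pair.

Norm tables use sample SD, skewness `g1 = m3/m2^{3/2}` and excess kurtosis
`m4/m2² − 3` from 1/n-normalized central moments, with minimum group sizes
2/3/4 respectively (NaN below).

## Problem sizes and tolerances in the shipped checks

The test suite and `scripts/acceptance.py` use cohorts of 90–102 subjects
(60+30 females mirroring a 2:1 healthy:disordered ratio, plus a small male
group), 250 ms recordings at 4 kHz / 40 kHz, 200–1000 permutations and 200
null replicates for FDR calibration — sizes at which every check is exact
or its sampling error is an order of magnitude below the asserted
tolerance. SNR-recovery tolerances are ±2 dB (HNR/SNR_Q) and ±3 dB (SNR_K);
cross-modal F0 agreement 1%; symmetry recovery ±1 GAW sample per period.

## What passing tests do and do not show

The generator produces stationary, single-vowel, well-segmented signals
with Gaussian perturbations and a fixed pulse shape. Passing recovery tests
shows the estimators are correct on signals whose ground truth is known; it
does not validate against clinical variability — real GAWs carry
segmentation error, camera-angle drift, irregular pulse shapes, and
non-Gaussian, temporally correlated perturbation, and real acoustics carry
room noise and vocal-tract variation none of which are modelled. Norm-table
values computed on synthetic cohorts characterize the generator, not any
clinical population. The disordered samplers are spread-widening devices,
not models of functional dysphonia.

## Known limitations

- Cycle detection assumes one dominant peak per cycle; severely aperiodic
  (type-III) signals raise errors rather than degrade gracefully.
- HNR/SNR_Q inherit cycle-boundary error: with boundaries detected on a
  noisy signal itself, peak wander costs a few dB relative to the injected
  SNR (recovery is exact with clean boundaries).
- CPP is computed on the single 250 ms segment (no frame averaging); the
  frame-averaged smoothed variant is deliberately out of scope.
- The acoustic model is a minimal source–filter chain; no radiation
  characteristic, no formant transitions, no aspiration-noise modulation.
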