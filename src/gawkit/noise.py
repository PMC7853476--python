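"""Spectral and waveform-matching noise measures.

Periodic (harmonic) versus aperiodic (noise) energy is quantified along two
routes:

* cepstral / spectral: CPP (cepstral peak prominence), NNE (normalized noise
  energy) and the frame-wise Klingholz signal-to-noise ratio SNR_K, which
  split the magnitude spectrum into harmonic bands around multiples of the
  fundamental and inter-harmonic bands;
* waveform-matching: HNR (harmonics-to-noise ratio against the length-
  normalized mean cycle waveform), the waveform-matching coefficients
  WMC_Max / WMC_Mean (adjacent-cycle correlations) and SNR_Q (mean-waveform
  versus residual energy over the whole segment).

All measures are in dB except the WMC correlations, and all are invariant
to uniform amplitude scaling.  Noise-free periodic inputs drive the
waveform-matching ratios to a +60 dB cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cycles import CycleSet, F0_MAX_HZ, F0_MIN_HZ
from .errors import ConfigurationError, DegenerateSignalError, TooFewCyclesError

__all__ = [
    "SpectralConfig",
    "cpp",
    "hnr_waveform",
    "wmc",
    "nne",
    "snr_klingholz",
    "snr_qi",
]

HNR_CAP_DB = 60.0


@dataclass
class SpectralConfig:
    """Shared knobs for the spectral noise measures.

    ``harmonic_bw_frac`` sets the width of each harmonic band as a fraction
    of f0 (band = k*f0 +/- f0*harmonic_bw_frac/2); ``band_max_hz`` caps the
    analysis band (None = Nyquist; 5 kHz is used for acoustic tracks);
    ``frame_cycles`` is the Klingholz frame length in cycles;
    ``cpp_trend_quefrency_s`` is the quefrency range of the cepstral trend
    line.  The cepstral peak is searched in [1/400, 1/80] s, the admissible
    phonation band.
    """

    harmonic_bw_frac: float = 0.25
    band_max_hz: float | None = None
    frame_cycles: int = 4
    cpp_trend_quefrency_s: tuple[float, float] = (1e-3, 12.5e-3)
    quefrency_band_s: tuple[float, float] = (1.0 / F0_MAX_HZ, 1.0 / F0_MIN_HZ)

    def validate(self) -> None:
        if self.harmonic_bw_frac <= 0:
            raise ConfigurationError("harmonic_bw_frac must be positive")
        if self.frame_cycles < 1:
            raise ConfigurationError("frame_cycles must be >= 1")


def _next_pow2(n: int) -> int:
    return int(2 ** np.ceil(np.log2(max(n, 2))))


def cpp(signal, fs, cfg: SpectralConfig | None = None, return_quefrency: bool = False):
    """Cepstral peak prominence (dB) of the whole segment.

    The Hann-windowed, zero-padded segment's log-magnitude spectrum (dB) is
    transformed to the real cepstrum; the peak inside the phonation
    quefrency band is measured against a least-squares line fitted to the
    cepstrum over the trend range (default 1-12.5 ms).
    """
    cfg = cfg or SpectralConfig()
    cfg.validate()
    x = np.asarray(signal, float)
    if not np.any(x != 0):
        raise DegenerateSignalError("all-zero signal: CPP undefined")
    x = (x - x.mean()) * np.hanning(len(x))
    nfft = max(_next_pow2(len(x)), 1024)
    spec = np.abs(np.fft.rfft(x, nfft))
    spec_db = 20.0 * np.log10(np.maximum(spec, 1e-300))
    ceps = np.fft.irfft(spec_db, nfft)
    quef = np.arange(nfft) / fs

    lo, hi = cfg.quefrency_band_s
    band = (quef >= lo) & (quef <= hi)
    if not band.any():
        raise ConfigurationError("quefrency band empty at this sampling rate")
    i_peak = np.flatnonzero(band)[np.argmax(ceps[band])]

    t_lo, t_hi = cfg.cpp_trend_quefrency_s
    trend = (quef >= t_lo) & (quef <= t_hi)
    coef = np.polyfit(quef[trend], ceps[trend], 1)
    baseline = np.polyval(coef, quef[i_peak])
    prominence = float(ceps[i_peak] - baseline)
    if return_quefrency:
        return prominence, float(quef[i_peak])
    return prominence


def _cycle_segments(signal, cycles: CycleSet):
    x = np.asarray(signal, float)
    return [x[a:b] for a, b in cycles.slices()]


def _resample_to(seg: np.ndarray, m: int) -> np.ndarray:
    """Linear length-normalization of one cycle to m samples."""
    if len(seg) == m:
        return seg
    src = np.linspace(0.0, 1.0, len(seg))
    dst = np.linspace(0.0, 1.0, m)
    return np.interp(dst, src, seg)


def _mean_waveform(signal, cycles: CycleSet):
    segs = _cycle_segments(signal, cycles)
    m = int(round(np.mean([len(s) for s in segs])))
    stack = np.vstack([_resample_to(s, m) for s in segs])
    return stack, stack.mean(axis=0)


def hnr_waveform(signal, cycles: CycleSet) -> float:
    """Harmonics-to-noise ratio (dB) by mean-waveform matching.

    Cycles are length-normalized to the rounded mean cycle length, the mean
    waveform is the harmonic estimate and per-cycle deviations from it the
    noise; capped at +60 dB for (near) noise-free inputs.
    """
    if cycles.n_cycles < 3:
        raise TooFewCyclesError("HNR needs at least 3 complete cycles")
    stack, mean_w = _mean_waveform(signal, cycles)
    num = stack.shape[0] * float(np.sum(mean_w**2))
    den = float(np.sum((stack - mean_w) ** 2))
    if den <= num * 10 ** (-HNR_CAP_DB / 10):
        return HNR_CAP_DB
    return float(10.0 * np.log10(num / den))


def wmc(signal, cycles: CycleSet) -> tuple[float, float]:
    """(WMC_Max, WMC_Mean): adjacent-cycle waveform correlations.

    Each adjacent pair is resampled to a common length and correlated;
    constant cycles are skipped.
    """
    if cycles.n_cycles < 3:
        raise TooFewCyclesError("WMC needs at least 3 complete cycles")
    segs = _cycle_segments(signal, cycles)
    vals = []
    for s1, s2 in zip(segs[:-1], segs[1:]):
        m = int(round((len(s1) + len(s2)) / 2))
        a = _resample_to(s1, m)
        b = _resample_to(s2, m)
        if a.std() == 0 or b.std() == 0:
            continue
        vals.append(float(np.corrcoef(a, b)[0, 1]))
    if not vals:
        raise DegenerateSignalError("all adjacent cycle pairs constant")
    return float(np.max(vals)), float(np.mean(vals))


def _harmonic_mask(freqs: np.ndarray, f0: float, bw_hz: float, band_max: float):
    """Boolean masks (analysis band, harmonic bins) on an rfft frequency grid.

    The harmonic half-width is never narrower than 1.5 frequency bins so the
    window mainlobe of an on-bin harmonic stays inside its band.
    """
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
    half = max(bw_hz / 2.0, 1.5 * df)
    in_band = (freqs > 0) & (freqs <= band_max)
    k = np.round(freqs / f0)
    near = np.abs(freqs - k * f0) <= half
    harmonic = in_band & near & (k >= 1)
    return in_band, harmonic


def nne(signal, fs, f0_mean, cfg: SpectralConfig | None = None) -> float:
    """Normalized noise energy (dB): inter-harmonic over total energy.

    The Hann-windowed magnitude spectrum inside the analysis band is split
    into harmonic bands (k*f0 +/- f0*harmonic_bw_frac/2) and the rest;
    NNE = 10 log10(E_interharmonic / E_total) <= 0.
    """
    cfg = cfg or SpectralConfig()
    cfg.validate()
    if not F0_MIN_HZ <= f0_mean <= F0_MAX_HZ:
        raise ConfigurationError(f"f0_mean={f0_mean} outside {F0_MIN_HZ}-{F0_MAX_HZ} Hz")
    x = np.asarray(signal, float)
    x = (x - x.mean()) * np.hanning(len(x))
    spec2 = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    band_max = cfg.band_max_hz if cfg.band_max_hz is not None else fs / 2.0
    in_band, harmonic = _harmonic_mask(freqs, f0_mean, cfg.harmonic_bw_frac * f0_mean, band_max)
    e_total = float(spec2[in_band].sum())
    if e_total <= 0:
        raise DegenerateSignalError("zero spectral energy")
    e_inter = float(spec2[in_band & ~harmonic].sum())
    return float(10.0 * np.log10(max(e_inter, 1e-300) / e_total))


def snr_klingholz(signal, fs, cycles: CycleSet, cfg: SpectralConfig | None = None):
    """(SNR_K [Mean], SNR_K [Std]) in dB over frames of ``frame_cycles`` cycles.

    Per frame, the inter-harmonic spectral density is extrapolated over the
    whole analysis band to estimate the noise energy; the harmonic energy is
    the remainder of the total.  Frame f0 comes from the frame's own cycle
    lengths, which keeps harmonics on-bin for unpadded frames.
    """
    cfg = cfg or SpectralConfig()
    cfg.validate()
    x = np.asarray(signal, float)
    b = cycles.boundaries
    k = cfg.frame_cycles
    n_frames = cycles.n_cycles // k
    if n_frames < 2:
        raise TooFewCyclesError(
            f"need at least 2 frames of {k} cycles, have {cycles.n_cycles} cycles"
        )
    band_max = cfg.band_max_hz if cfg.band_max_hz is not None else fs / 2.0
    vals = []
    for j in range(n_frames):
        a, e = b[j * k], b[(j + 1) * k]
        frame = x[a:e]
        f0 = k * fs / (e - a)
        w = (frame - frame.mean()) * np.hanning(len(frame))
        spec2 = np.abs(np.fft.rfft(w)) ** 2
        freqs = np.fft.rfftfreq(len(w), d=1.0 / fs)
        in_band, harmonic = _harmonic_mask(freqs, f0, cfg.harmonic_bw_frac * f0, band_max)
        noise_bins = in_band & ~harmonic
        e_total = float(spec2[in_band].sum())
        n_in, n_noise = int(in_band.sum()), int(noise_bins.sum())
        if e_total <= 0 or n_noise == 0:
            continue
        e_noise = float(spec2[noise_bins].mean()) * n_in  # density extrapolated
        e_harm = max(e_total - e_noise, e_total * 1e-10)
        e_noise = max(e_noise, e_total * 1e-10)
        vals.append(10.0 * np.log10(e_harm / e_noise))
    if len(vals) < 2:
        raise TooFewCyclesError("fewer than 2 usable frames")
    vals = np.asarray(vals)
    return float(vals.mean()), float(vals.std(ddof=1))


def snr_qi(signal, cycles: CycleSet) -> float:
    """SNR_Q (dB): mean-waveform energy vs residual energy in the original
    cycle domain.

    The length-normalized mean waveform is stretched back to each cycle's own
    length; residuals are taken sample-wise in that domain, summed over the
    whole segment.  Capped at +60 dB.
    """
    if cycles.n_cycles < 3:
        raise TooFewCyclesError("SNR_Q needs at least 3 complete cycles")
    segs = _cycle_segments(signal, cycles)
    m = int(round(np.mean([len(s) for s in segs])))
    mean_w = np.vstack([_resample_to(s, m) for s in segs]).mean(axis=0)
    num = den = 0.0
    for seg in segs:
        est = _resample_to(mean_w, len(seg))
        num += float(np.sum(est**2))
        den += float(np.sum((seg - est) ** 2))
    if den <= num * 10 ** (-HNR_CAP_DB / 10):
        return HNR_CAP_DB
    return float(10.0 * np.log10(num / den))
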