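"""Synthetic cohorts of paired glottal-area / acoustic recordings.

Real data for this kind of study comes from high-speed videoendoscopy of the
vibrating vocal folds (glottal area waveform, GAW, at the video frame rate)
with a synchronously recorded microphone track.  This module emulates that
setup for sustained /i/ phonation with a fully controlled ground truth:

* a quasi-periodic glottal pulse train (80-400 Hz) with half-cosine opening
  and closing ramps, a flat closed plateau and a residual closure gap;
* cycle-to-cycle period jitter and amplitude shimmer injected as truncated
  Gaussian multiplicative noise;
* a left/right split of the area with a controllable amplitude ratio and
  phase delay (GAW_T = GAW_L + GAW_R holds exactly, by construction);
* an acoustic counterpart built from the *same* pulse train by a simple
  source-filter model: first difference of the area pulse fed through a bank
  of two-pole resonators (vowel-/i/-like formants), plus white noise at a
  configurable SNR.

All randomness flows from one master seed; each recording of a cohort gets
its own child stream so cohorts are reproducible element-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, GawkitError
from .io import GROUPS, Recording

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "glottal_pulse",
    "simulate_recording",
    "simulate_cohort",
    "default_group_sampler",
]

#: vowel-/i/-like resonances: (center frequency Hz, bandwidth Hz)
DEFAULT_FORMANTS = ((300.0, 80.0), (2300.0, 150.0), (3000.0, 200.0))


@dataclass
class SynthConfig:
    """Controls for one synthetic recording.

    The cycle layout (as fractions of the period) is: a closed plateau of
    ``plateau_frac`` at the residual-gap level, an opening half-cosine ramp,
    a closing half-cosine ramp (together ``open_quotient`` of the period,
    split by ``closing_fraction``), and any remaining closed time after the
    closing ramp.  ``plateau_frac + open_quotient`` may not exceed 1; keeping
    it equal to 1 makes ``plateau_frac`` the exact realized closed fraction.
    """

    f0_hz: float = 140.0
    jitter_rel: float = 0.0
    shimmer_rel: float = 0.0
    open_quotient: float = 0.7
    closing_fraction: float = 0.45
    plateau_frac: float = 0.3
    gap_rel: float = 0.0
    lr_amp_ratio: float = 1.0
    lr_phase_delay_rel: float = 0.0
    acoustic_snr_db: float = np.inf
    gaw_noise_rel: float = 0.0
    duration_s: float = 0.25
    fs_gaw: int = 4000
    fs_acoustic: int = 40000
    formants_hz: Sequence[tuple[float, float]] = DEFAULT_FORMANTS
    seed: int = 0

    def validate(self) -> None:
        if not 80.0 <= self.f0_hz <= 400.0:
            raise ConfigurationError(f"f0_hz={self.f0_hz} outside 80-400 Hz")
        if not 0.0 < self.open_quotient <= 1.0:
            raise ConfigurationError("open_quotient must be in (0, 1]")
        if not 0.0 <= self.closing_fraction <= 1.0:
            raise ConfigurationError("closing_fraction must be in [0, 1]")
        if not 0.0 <= self.plateau_frac < 1.0:
            raise ConfigurationError("plateau_frac must be in [0, 1)")
        if self.plateau_frac + self.open_quotient > 1.0 + 1e-12:
            raise ConfigurationError(
                "plateau_frac + open_quotient exceeds one cycle "
                f"({self.plateau_frac} + {self.open_quotient})"
            )
        if not 0.0 <= self.gap_rel < 1.0:
            raise ConfigurationError("gap_rel must be in [0, 1)")
        if self.lr_amp_ratio <= 0:
            raise ConfigurationError("lr_amp_ratio must be positive")
        if not -0.5 <= self.lr_phase_delay_rel <= 0.5:
            raise ConfigurationError("lr_phase_delay_rel must be in [-0.5, 0.5]")
        if self.jitter_rel < 0 or self.shimmer_rel < 0 or self.gaw_noise_rel < 0:
            raise ConfigurationError("noise levels must be non-negative")
        if self.fs_acoustic % self.fs_gaw != 0:
            raise ConfigurationError(
                "fs_acoustic must be an integer multiple of fs_gaw"
            )


@dataclass
class GroundTruth:
    """What was actually emitted, recomputed from the generated pulse train.

    ``periods_samples`` and ``amplitudes`` are the realized per-cycle values
    (after integer rounding of periods and truncation of perturbations), so
    recovery tests compare against what the arrays really contain rather than
    the requested configuration.
    """

    periods_samples: np.ndarray
    amplitudes: np.ndarray
    onsets_samples: np.ndarray
    mean_period_s: float
    jitter_rel: float          # std(T)/mean(T) of realized periods
    shimmer_rel: float         # std(A)/mean(A) of realized amplitudes
    gap_rel: float
    lr_amp_ratio: float
    lr_phase_delay_rel: float
    acoustic_snr_db: float
    plateau_frac: float = 0.0


def glottal_pulse(phase, cfg: SynthConfig):
    """Unit glottal-area pulse evaluated at cycle phase(s) in [0, 1).

    Returns ``gap_rel`` during the closed plateau, rises to 1 over the
    opening half-cosine, falls back over the closing half-cosine.  Accepts
    scalars or arrays.
    """
    cfg.validate()
    phase = np.asarray(phase, dtype=float)
    if np.any(phase < 0) or np.any(phase >= 1):
        raise ValueError("phase must lie in [0, 1)")
    p_open = cfg.plateau_frac
    d_rise = cfg.open_quotient * (1.0 - cfg.closing_fraction)
    d_fall = cfg.open_quotient * cfg.closing_fraction
    p_peak = p_open + d_rise
    p_close = p_peak + d_fall

    shape = np.zeros_like(phase)
    if d_rise > 0:
        m = (phase >= p_open) & (phase < p_peak)
        u = (phase[m] - p_open) / d_rise
        shape[m] = 0.5 * (1.0 - np.cos(np.pi * u))
    if d_fall > 0:
        m = (phase >= p_peak) & (phase < p_close)
        u = (phase[m] - p_peak) / d_fall
        shape[m] = 0.5 * (1.0 + np.cos(np.pi * u))
    if d_rise == 0 and d_fall > 0:
        pass  # pure closing ramp already handled
    out = cfg.gap_rel + (1.0 - cfg.gap_rel) * shape
    return out if out.ndim else float(out)


def _draw_cycles(cfg: SynthConfig, rng: np.random.Generator):
    """Integer per-cycle periods (GAW samples) and amplitudes covering the segment."""
    n_gaw = int(round(cfg.duration_s * cfg.fs_gaw))
    t0 = cfg.fs_gaw / cfg.f0_hz
    periods, amps = [], []
    total = 0
    while total < n_gaw + int(np.ceil(t0)) + 1:
        eps_t = np.clip(rng.standard_normal() * cfg.jitter_rel, -3 * cfg.jitter_rel, 3 * cfg.jitter_rel) if cfg.jitter_rel > 0 else 0.0
        eps_a = np.clip(rng.standard_normal() * cfg.shimmer_rel, -3 * cfg.shimmer_rel, 3 * cfg.shimmer_rel) if cfg.shimmer_rel > 0 else 0.0
        p = max(4, int(round(t0 * (1.0 + eps_t))))
        periods.append(p)
        amps.append(max(0.05, 1.0 + eps_a))
        total += p
    return n_gaw, np.array(periods, dtype=int), np.array(amps)


def _pulse_train(cfg, periods, amps, n_samples, rate_factor, phase_offset=0.0):
    """Evaluate the pulse train on a grid ``rate_factor`` times the GAW rate."""
    onsets = np.concatenate([[0], np.cumsum(periods)]) * rate_factor
    out = np.empty(n_samples)
    for k, (p, a) in enumerate(zip(periods * rate_factor, amps)):
        b = onsets[k]
        if b >= n_samples:
            break
        e = min(b + p, n_samples)
        phase = (np.arange(b, e) - b) / p
        phase = np.mod(phase - phase_offset, 1.0)
        out[b:e] = a * glottal_pulse(phase, cfg)
    return out


def simulate_recording(cfg: SynthConfig, subject_id: str = "synth", group: str = "NF"):
    """Generate one paired recording plus its ground truth.

    GAW_L is the delayed, amplitude-scaled half; GAW_R the complementary
    half; GAW_T their sample-wise sum.  The acoustic track is built from the
    same pulse train evaluated on the audio grid, first-differenced, passed
    through the formant resonator bank and mixed with white noise at
    ``acoustic_snr_db``.
    """
    cfg.validate()
    if cfg.duration_s * cfg.f0_hz < 3:
        raise GawkitError("duration too short for at least 3 cycles")
    rng = np.random.default_rng([cfg.seed, 2**20])
    n_gaw, periods, amps = _draw_cycles(cfg, rng)

    r = cfg.lr_amp_ratio
    w_left = r / (1.0 + r)
    w_right = 1.0 / (1.0 + r)
    delay = cfg.lr_phase_delay_rel

    left = w_left * _pulse_train(cfg, periods, amps, n_gaw, 1, phase_offset=delay)
    right = w_right * _pulse_train(cfg, periods, amps, n_gaw, 1, phase_offset=0.0)
    if cfg.gaw_noise_rel > 0:
        peak = max(left.max(), right.max())
        left = left + rng.normal(0, cfg.gaw_noise_rel * peak, n_gaw)
        right = right + rng.normal(0, cfg.gaw_noise_rel * peak, n_gaw)
    total = left + right

    # acoustic: same cycle sequence on the fine grid, differentiated + filtered;
    # two warm-up cycles are prepended and trimmed so the resonator startup
    # transient does not bleed into the segment
    factor = cfg.fs_acoustic // cfg.fs_gaw
    n_ac = n_gaw * factor
    warm = np.full(2, periods[0])
    pad = int(warm.sum()) * factor
    src = _pulse_train(cfg, np.concatenate([warm, periods]),
                       np.concatenate([amps[:1].repeat(2), amps]),
                       n_ac + pad, factor)
    flow = np.diff(src, prepend=src[0])
    ac = flow
    for fc, bw in cfg.formants_hz:
        r_pole = np.exp(-np.pi * bw / cfg.fs_acoustic)
        theta = 2 * np.pi * fc / cfg.fs_acoustic
        a = [1.0, -2 * r_pole * np.cos(theta), r_pole**2]
        ac = sps.lfilter([1.0], a, ac)
    ac = ac[pad:]
    ac = ac / (np.max(np.abs(ac)) or 1.0)
    if np.isfinite(cfg.acoustic_snr_db):
        p_sig = np.mean(ac**2)
        p_noise = p_sig / 10 ** (cfg.acoustic_snr_db / 10)
        ac = ac + rng.normal(0, np.sqrt(p_noise), n_ac)

    onsets = np.concatenate([[0], np.cumsum(periods)])
    keep = onsets[1:] <= n_gaw
    periods_in = periods[keep]
    amps_in = amps[keep]
    gt = GroundTruth(
        periods_samples=periods_in,
        amplitudes=amps_in,
        onsets_samples=onsets[:-1][keep],
        mean_period_s=float(np.mean(periods_in)) / cfg.fs_gaw,
        jitter_rel=float(np.std(periods_in, ddof=1) / np.mean(periods_in)) if len(periods_in) > 1 else 0.0,
        shimmer_rel=float(np.std(amps_in, ddof=1) / np.mean(amps_in)) if len(amps_in) > 1 else 0.0,
        gap_rel=cfg.gap_rel,
        lr_amp_ratio=cfg.lr_amp_ratio,
        lr_phase_delay_rel=cfg.lr_phase_delay_rel,
        acoustic_snr_db=cfg.acoustic_snr_db,
        plateau_frac=1.0 - cfg.open_quotient,
    )
    rec = Recording(
        gaw_total=total,
        gaw_left=left,
        gaw_right=right,
        acoustic=ac,
        fs_gaw=cfg.fs_gaw,
        fs_acoustic=cfg.fs_acoustic,
        subject_id=subject_id,
        group=group,
    )
    return rec, gt


def default_group_sampler(group: str) -> Callable[[np.random.Generator], SynthConfig]:
    """Per-group config sampler emulating the four study groups.

    Female groups phonate higher (160-300 Hz) than male groups (80-160 Hz);
    the functionally disordered samplers shift jitter, shimmer, residual gap
    and left/right asymmetry upward.  The disordered levels are illustrative
    study conditions, not clinically calibrated distributions.
    """
    female = group in ("NF", "FDF")
    disordered = group in ("FDF", "FDM")

    def sample(rng: np.random.Generator) -> SynthConfig:
        f0 = rng.uniform(160, 300) if female else rng.uniform(90, 160)
        if disordered:
            jitter = rng.uniform(0.01, 0.03)
            shimmer = rng.uniform(0.04, 0.10)
            gap = rng.uniform(0.05, 0.30)
            delay = rng.uniform(-0.10, 0.10)
            ratio = rng.uniform(0.6, 1.4)
            snr = rng.uniform(15, 25)
        else:
            jitter = rng.uniform(0.002, 0.008)
            shimmer = rng.uniform(0.01, 0.04)
            gap = rng.uniform(0.0, 0.10)
            delay = rng.uniform(-0.02, 0.02)
            ratio = rng.uniform(0.9, 1.1)
            snr = rng.uniform(25, 35)
        oq = rng.uniform(0.55, 0.8)
        return SynthConfig(
            f0_hz=f0,
            jitter_rel=jitter,
            shimmer_rel=shimmer,
            open_quotient=oq,
            closing_fraction=rng.uniform(0.35, 0.55),
            plateau_frac=1.0 - oq,
            gap_rel=gap,
            lr_amp_ratio=ratio,
            lr_phase_delay_rel=delay,
            acoustic_snr_db=snr,
            gaw_noise_rel=rng.uniform(0.0, 0.02),
        )

    return sample


def simulate_cohort(
    n_per_group,
    cfg_sampler: Callable[[str], Callable] | None = None,
    seed: int = 0,
):
    """Simulate a cohort across the four groups.

    Parameters
    ----------
    n_per_group : sequence of 4 ints or mapping
        Counts for (NF, FDF, NM, FDM).
    cfg_sampler : callable, optional
        ``group -> (rng -> SynthConfig)``; defaults to
        :func:`default_group_sampler`.
    seed : int
        Master seed; recording ``i`` uses the child stream ``[seed, i]``.

    Returns
    -------
    list of (Recording, GroundTruth)
    """
    if isinstance(n_per_group, dict):
        counts = [int(n_per_group.get(g, 0)) for g in GROUPS]
    else:
        counts = [int(n) for n in n_per_group]
    if len(counts) != 4 or any(c < 0 for c in counts):
        raise ConfigurationError("n_per_group must give non-negative counts for NF, FDF, NM, FDM")
    sampler_for = cfg_sampler or default_group_sampler

    out = []
    idx = 0
    for group, n in zip(GROUPS, counts):
        sample = sampler_for(group)
        for _ in range(n):
            rng = np.random.default_rng([seed, idx])
            cfg = replace(sample(rng), seed=int(rng.integers(0, 2**31 - 1)))
            sid = f"{group}{idx:04d}"
            out.append(simulate_recording(cfg, subject_id=sid, group=group))
            idx += 1
    return out
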