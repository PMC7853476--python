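"""Per-cycle tables and fundamental-frequency / perturbation parameters.

Given a set of complete oscillation cycles, this module builds the per-cycle
table of period T_i, peak-to-peak amplitude A_i and mean-removed energy E_i,
and derives from it:

* F0 [Mean] / F0 [Std] — mean and sample standard deviation of the per-cycle
  instantaneous frequencies f_i = 1/T_i (Hz);
* MJit — mean absolute difference of adjacent periods (ms), and
  Jit(%) = 100 * MJit / mean period — relative jitter;
* PVI — period variability index, 100 * std(T)/mean(T);
* MShim — mean absolute adjacent-cycle amplitude ratio in dB,
  and AVI — sample std of 20*log10(A_i / mean(A)) (dB, acoustic track);
* EPF — energy perturbation factor, 100 * mean |E_{i+1}-E_i| / mean(E).

Sample (n-1) standard deviations are used throughout.  Amplitude is the
within-cycle max minus min, which makes the measures robust to the residual
closure-gap offset present in glottal area waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cycles import CycleSet
from .errors import DegenerateSignalError, TooFewCyclesError

__all__ = [
    "CycleTable",
    "cycle_table",
    "f0_stats",
    "jitter_measures",
    "amplitude_measures",
    "energy_perturbation",
]


@dataclass
class CycleTable:
    """Per complete cycle: period (s), peak-to-peak amplitude, energy."""

    periods_s: np.ndarray
    amplitudes: np.ndarray
    energies: np.ndarray

    def __post_init__(self):
        self.periods_s = np.asarray(self.periods_s, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if np.any(self.periods_s <= 0):
            raise ValueError("cycle periods must be positive")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")

    @property
    def n_cycles(self) -> int:
        return len(self.periods_s)


def cycle_table(signal, cycles: CycleSet) -> CycleTable:
    """Build the per-cycle T/A/E table from complete cycles."""
    x = np.asarray(signal, dtype=float)
    if cycles.n_cycles < 2:
        raise TooFewCyclesError("need at least 2 complete cycles")
    periods = np.diff(cycles.boundaries) / cycles.fs
    amps = np.empty(cycles.n_cycles)
    energies = np.empty(cycles.n_cycles)
    for i, (a, b) in enumerate(cycles.slices()):
        seg = x[a:b]
        amps[i] = seg.max() - seg.min()
        seg0 = seg - seg.mean()
        energies[i] = np.dot(seg0, seg0)
    return CycleTable(periods_s=periods, amplitudes=amps, energies=energies)


def f0_stats(table: CycleTable) -> tuple[float, float]:
    """(F0 [Mean], F0 [Std]) in Hz from the inverse cycle lengths."""
    if table.n_cycles < 2:
        raise TooFewCyclesError("F0 [Std] needs at least 2 cycles")
    f = 1.0 / table.periods_s
    return float(f.mean()), float(f.std(ddof=1))


def jitter_measures(table: CycleTable) -> tuple[float, float, float]:
    """(MJit in ms, Jit(%) in a.u., PVI in a.u.)."""
    if table.n_cycles < 3:
        raise TooFewCyclesError("jitter measures need at least 3 cycles")
    t_ms = table.periods_s * 1e3
    mjit = float(np.mean(np.abs(np.diff(t_ms))))
    jit_pct = 100.0 * mjit / float(t_ms.mean())
    pvi = 100.0 * float(t_ms.std(ddof=1) / t_ms.mean())
    return mjit, jit_pct, pvi


def amplitude_measures(table: CycleTable) -> tuple[float, float]:
    """(MShim in dB, AVI in dB).

    MShim averages |20 log10(A_{i+1}/A_i)| over adjacent pairs; AVI is the
    sample std of the amplitudes on a dB scale relative to their mean.
    """
    if table.n_cycles < 3:
        raise TooFewCyclesError("amplitude measures need at least 3 cycles")
    a = table.amplitudes
    if np.any(a <= 0):
        raise DegenerateSignalError("zero cycle amplitude: shimmer undefined")
    ratios_db = 20.0 * np.log10(a[1:] / a[:-1])
    mshim = float(np.mean(np.abs(ratios_db)))
    avi = float(np.std(20.0 * np.log10(a / a.mean()), ddof=1))
    return mshim, avi


def energy_perturbation(table: CycleTable) -> float:
    """EPF: relative mean absolute adjacent-cycle energy difference (a.u.)."""
    if table.n_cycles < 3:
        raise TooFewCyclesError("EPF needs at least 3 cycles")
    e = table.energies
    if e.mean() <= 0:
        raise DegenerateSignalError("zero cycle energies: EPF undefined")
    return 100.0 * float(np.mean(np.abs(np.diff(e))) / e.mean())
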