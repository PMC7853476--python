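"""Oscillation-cycle detection on GAW and acoustic signals.

Cycles are delimited at successive local maxima ("maximum-based") or minima
("minimum-based") of the quasi-periodic signal.  A cycle is the half-open
sample interval [b_i, b_{i+1}); partial cycles at the segment edges are
discarded, so every downstream per-cycle parameter sees complete cycles
only.  Vocal-fold oscillation during normal phonation lies between 80 and
400 Hz, which bounds the admissible lag range of the dominant-period search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import AlignmentError, DegenerateSignalError, TooFewCyclesError, UnvoicedSignalError

F0_MIN_HZ = 80.0
F0_MAX_HZ = 400.0

#: minimum normalized-autocorrelation value accepted as a voicing peak
MIN_AUTOCORR = 0.2
#: peak prominence threshold, as a fraction of the signal's peak-to-peak range
MIN_PROMINENCE_FRAC = 0.2
#: minimum inter-peak spacing, as a fraction of the dominant period
MIN_SPACING_FRAC = 0.5


@dataclass
class CycleSet:
    """Ordered cycle boundaries on one signal.

    ``boundaries`` are strictly increasing 0-based sample indices; cycle i is
    ``[boundaries[i], boundaries[i+1])``.  ``basis`` records whether the
    boundaries sit on local maxima or minima.
    """

    boundaries: np.ndarray
    basis: str
    fs: float
    n_samples: int | None = None

    def __post_init__(self):
        self.boundaries = np.asarray(self.boundaries, dtype=int)
        if self.basis not in ("maximum", "minimum"):
            raise ValueError(f"basis must be 'maximum' or 'minimum', got {self.basis!r}")
        if len(self.boundaries) >= 2:
            d = np.diff(self.boundaries)
            if np.any(d < 2):
                raise ValueError("every cycle must span at least 2 samples")
            if np.any(d <= 0):
                raise ValueError("boundaries must be strictly increasing")

    @property
    def n_cycles(self) -> int:
        return max(len(self.boundaries) - 1, 0)

    def periods_s(self) -> np.ndarray:
        return np.diff(self.boundaries) / self.fs

    def slices(self):
        """Half-open (start, stop) pairs, one per complete cycle."""
        return [(int(a), int(b)) for a, b in zip(self.boundaries[:-1], self.boundaries[1:])]


def estimate_dominant_period(signal, fs) -> int:
    """Dominant oscillation period in samples via normalized autocorrelation.

    The mean-removed autocorrelation is searched over lags corresponding to
    80-400 Hz; the argmax is returned.  Raises if the signal is constant or
    no autocorrelation value in the band exceeds ``MIN_AUTOCORR``.
    """
    x = np.asarray(signal, dtype=float)
    x = x - x.mean()
    e0 = np.dot(x, x)
    if e0 <= 0:
        raise DegenerateSignalError("constant signal: no period")
    lag_min = max(2, int(np.floor(fs / F0_MAX_HZ)))
    lag_max = int(np.ceil(fs / F0_MIN_HZ))
    if len(x) < 4 * lag_min:
        raise DegenerateSignalError("signal too short for period estimation")
    lag_max = min(lag_max, len(x) - 1)
    n = len(x)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(spec * np.conj(spec), nfft)[: lag_max + 1]
    ac = ac / e0
    band = ac[lag_min : lag_max + 1]
    if band.max() < MIN_AUTOCORR:
        raise UnvoicedSignalError(
            f"no autocorrelation peak above {MIN_AUTOCORR} in the 80-400 Hz band"
        )
    return lag_min + int(np.argmax(band))


def detect_cycles(signal, fs, basis: str = "maximum") -> CycleSet:
    """Detect maximum- or minimum-based cycles.

    Peaks (troughs, via negation, for ``basis='minimum'``) must be separated
    by at least half the dominant period and have prominence of at least 20%
    of the signal's peak-to-peak range; the thresholds are module constants.
    """
    x = np.asarray(signal, dtype=float)
    if basis == "minimum":
        x = -x
    elif basis != "maximum":
        raise ValueError(f"unknown basis {basis!r}")
    period = estimate_dominant_period(x, fs)
    ptp = np.ptp(x)
    peaks, _ = find_peaks(
        x,
        distance=max(1, int(MIN_SPACING_FRAC * period)),
        prominence=MIN_PROMINENCE_FRAC * ptp,
    )
    if len(peaks) < 3:
        raise TooFewCyclesError(
            f"found {len(peaks)} {basis}-based boundaries; need at least 3"
        )
    return CycleSet(boundaries=peaks, basis=basis, fs=fs, n_samples=len(x))


def transfer_cycles(cycles: CycleSet, target_signal) -> CycleSet:
    """Re-attach boundaries detected on one signal to another of equal length.

    Used to carry GAW_T cycles over to GAW_L and GAW_R so all three halves
    share the same cycle grid; no re-detection is performed.
    """
    target = np.asarray(target_signal)
    if cycles.n_samples is not None and len(target) != cycles.n_samples:
        raise AlignmentError(
            f"target length {len(target)} does not match source length {cycles.n_samples}"
        )
    if len(target) <= cycles.boundaries[-1]:
        raise AlignmentError(
            f"target length {len(target)} shorter than last boundary "
            f"{cycles.boundaries[-1]}"
        )
    return CycleSet(
        boundaries=cycles.boundaries.copy(),
        basis=cycles.basis,
        fs=cycles.fs,
        n_samples=cycles.n_samples,
    )


def cycles_to_frame(cycles: CycleSet):
    """CycleSet as a (cycle_index, start_sample, end_sample) DataFrame."""
    import pandas as pd

    sl = cycles.slices()
    return pd.DataFrame(
        {
            "cycle_index": np.arange(len(sl)),
            "start_sample": [a for a, _ in sl],
            "end_sample": [b for _, b in sl],
        }
    )
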