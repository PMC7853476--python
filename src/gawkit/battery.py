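"""Assembly of the 49-parameter voice battery for one recording.

Per recording the battery emits 35 GAW-based parameters (25 computed on the
total glottal area waveform plus 10 left/right symmetry parameters) and 14
acoustic parameters.  Cycle handling follows the measurement convention of
the underlying modules: maximum-based cycles are detected independently on
GAW_T and on the acoustic track; GAW_T cycles are transferred to GAW_L and
GAW_R (never re-detected); the phase-asymmetry parameters use minimum-based
GAW_T cycles so each cycle contains one complete opening peak.

Parameter names are frozen, unit-suffixed strings (schema-versioned) such as
``gaw_F0_Mean_Hz`` or ``ac_CPP_dB`` so cohort CSVs are stable.  When a
sub-computation fails (unvoiced track, too few cycles...) the affected
entries are emitted as NaN with the failure recorded in
``ParameterVector.flags`` — never silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dynamics, noise, perturb, symmetry
from .cycles import detect_cycles, transfer_cycles
from .errors import GawkitError
from .io import Recording

__all__ = ["ParameterVector", "PARAMETER_SCHEMA", "gaw_parameter_names",
           "acoustic_parameter_names", "extract_parameters", "cohort_parameters"]

SCHEMA_VERSION = "battery-1"

#: duration the study protocol selects from each sustained phonation
EXPECTED_DURATION_S = 0.25
DURATION_TOL_S = 0.005

# (name, source signal, unit); order is frozen
PARAMETER_SCHEMA: tuple[tuple[str, str, str], ...] = (
    # --- acoustic (14) ---
    ("F0_Mean", "ac", "Hz"),
    ("F0_Std", "ac", "Hz"),
    ("MJit", "ac", "ms"),
    ("JitPct", "ac", "au"),
    ("PVI", "ac", "au"),
    ("MShim", "ac", "dB"),
    ("AVI", "ac", "dB"),
    ("CPP", "ac", "dB"),
    ("HNR", "ac", "dB"),
    ("WMC_Max", "ac", "au"),
    ("WMC_Mean", "ac", "au"),
    ("NNE", "ac", "dB"),
    ("SNRK_Mean", "ac", "dB"),
    ("SNRK_Std", "ac", "dB"),
    # --- GAW, non-symmetry (25) ---
    ("F0_Mean", "gaw", "Hz"),
    ("F0_Std", "gaw", "Hz"),
    ("MJit", "gaw", "ms"),
    ("JitPct", "gaw", "au"),
    ("PVI", "gaw", "au"),
    ("MShim", "gaw", "dB"),
    ("EPF", "gaw", "au"),
    ("CQ_Mean", "gaw", "au"),
    ("CQ_Std", "gaw", "au"),
    ("SQ_Mean", "gaw", "au"),
    ("SQ_Std", "gaw", "au"),
    ("GGI_Mean", "gaw", "au"),
    ("GGI_Std", "gaw", "au"),
    ("PQ_Mean", "gaw", "au"),
    ("PQ_Std", "gaw", "au"),
    ("GAI_Mean", "gaw", "au"),
    ("GAI_Std", "gaw", "au"),
    ("CPP", "gaw", "dB"),
    ("HNR", "gaw", "dB"),
    ("WMC_Max", "gaw", "au"),
    ("WMC_Mean", "gaw", "au"),
    ("NNE", "gaw", "dB"),
    ("SNRK_Mean", "gaw", "dB"),
    ("SNRK_Std", "gaw", "dB"),
    ("SNRQ", "gaw", "dB"),
    # --- GAW, left/right symmetry (10) ---
    ("PhA_Mean", "gaw", "au"),
    ("PhAI_Mean", "gaw", "au"),
    ("PhAI_Std", "gaw", "au"),
    ("AmS_Mean", "gaw", "au"),
    ("AmSI_Mean", "gaw", "au"),
    ("AmSI_Std", "gaw", "au"),
    ("SpS_Mean", "gaw", "au"),
    ("SpSI_Mean", "gaw", "au"),
    ("SpSI_Std", "gaw", "au"),
    ("WaSI_Mean", "gaw", "au"),
)


def _column(name: str, signal: str, unit: str) -> str:
    return f"{signal}_{name}_{unit}"


#: frozen column order of the 49-entry vector
PARAMETER_COLUMNS: tuple[str, ...] = tuple(_column(*row) for row in PARAMETER_SCHEMA)


def gaw_parameter_names() -> list[str]:
    """The 35 GAW-based parameter columns (non-symmetry + symmetry)."""
    return [_column(n, s, u) for n, s, u in PARAMETER_SCHEMA if s == "gaw"]


def acoustic_parameter_names() -> list[str]:
    """The 14 acoustic parameter columns."""
    return [_column(n, s, u) for n, s, u in PARAMETER_SCHEMA if s == "ac"]


@dataclass
class ParameterVector:
    """The 49 named parameter values for one recording.

    ``values`` maps every schema column to a float (NaN when the
    sub-computation failed); ``flags`` collects human-readable failure
    reasons keyed by the failing stage.
    """

    subject_id: str
    group: str
    values: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        for col in PARAMETER_COLUMNS:
            self.values.setdefault(col, np.nan)

    @property
    def n_missing(self) -> int:
        return int(sum(np.isnan(v) for v in self.values.values()))

    def to_row(self) -> dict:
        row = {"subject_id": self.subject_id, "group": self.group}
        row.update({c: self.values[c] for c in PARAMETER_COLUMNS})
        return row


def _perturbation_block(out, signal_name, table):
    f0_mean, f0_std = perturb.f0_stats(table)
    mjit, jit, pvi = perturb.jitter_measures(table)
    mshim, avi = perturb.amplitude_measures(table)
    out[f"{signal_name}_F0_Mean_Hz"] = f0_mean
    out[f"{signal_name}_F0_Std_Hz"] = f0_std
    out[f"{signal_name}_MJit_ms"] = mjit
    out[f"{signal_name}_JitPct_au"] = jit
    out[f"{signal_name}_PVI_au"] = pvi
    out[f"{signal_name}_MShim_dB"] = mshim
    return f0_mean, avi


def _noise_block(out, signal_name, x, fs, cyc, f0_mean, spectral_cfg):
    out[f"{signal_name}_CPP_dB"] = noise.cpp(x, fs, spectral_cfg)
    out[f"{signal_name}_HNR_dB"] = noise.hnr_waveform(x, cyc)
    wmax, wmean = noise.wmc(x, cyc)
    out[f"{signal_name}_WMC_Max_au"] = wmax
    out[f"{signal_name}_WMC_Mean_au"] = wmean
    out[f"{signal_name}_NNE_dB"] = noise.nne(x, fs, f0_mean, spectral_cfg)
    sk_mean, sk_std = noise.snr_klingholz(x, fs, cyc, spectral_cfg)
    out[f"{signal_name}_SNRK_Mean_dB"] = sk_mean
    out[f"{signal_name}_SNRK_Std_dB"] = sk_std


def extract_parameters(rec: Recording) -> ParameterVector:
    """Compute the full 49-entry parameter vector for one recording.

    Failures are isolated per track: an unusable acoustic track leaves the
    35 GAW entries intact (and vice versa), with NaNs and a flag for the
    failed side.  Deterministic for fixed input.
    """
    pv = ParameterVector(subject_id=rec.subject_id, group=rec.group)
    out = pv.values

    if abs(rec.duration_s - EXPECTED_DURATION_S) > DURATION_TOL_S:
        warnings.warn(
            f"{rec.subject_id or 'recording'}: duration {rec.duration_s:.3f}s "
            f"outside {EXPECTED_DURATION_S}±{DURATION_TOL_S}s",
            stacklevel=2,
        )

    # ---- GAW side -------------------------------------------------------
    try:
        cyc_max = detect_cycles(rec.gaw_total, rec.fs_gaw, basis="maximum")
        table = perturb.cycle_table(rec.gaw_total, cyc_max)
        f0_mean, _ = _perturbation_block(out, "gaw", table)
        out["gaw_EPF_au"] = perturb.energy_perturbation(table)

        lm = dynamics.phase_landmarks(rec.gaw_total, cyc_max)
        cq_m, cq_s, sq_m, sq_s, pq_m, pq_s = dynamics.quotients(lm)
        out["gaw_CQ_Mean_au"], out["gaw_CQ_Std_au"] = cq_m, cq_s
        out["gaw_SQ_Mean_au"], out["gaw_SQ_Std_au"] = sq_m, sq_s
        out["gaw_PQ_Mean_au"], out["gaw_PQ_Std_au"] = pq_m, pq_s
        ggi_m, ggi_s, gai_m, gai_s = dynamics.gap_indices(rec.gaw_total, cyc_max)
        out["gaw_GGI_Mean_au"], out["gaw_GGI_Std_au"] = ggi_m, ggi_s
        out["gaw_GAI_Mean_au"], out["gaw_GAI_Std_au"] = gai_m, gai_s

        gaw_spectral = noise.SpectralConfig()
        _noise_block(out, "gaw", rec.gaw_total, rec.fs_gaw, cyc_max, f0_mean, gaw_spectral)
        out["gaw_SNRQ_dB"] = noise.snr_qi(rec.gaw_total, cyc_max)

        # symmetry: amplitude/spatial/waveform on transferred maximum cycles,
        # phase on minimum-based cycles
        cyc_l = transfer_cycles(cyc_max, rec.gaw_left)
        ams, amsi_m, amsi_s = symmetry.amplitude_symmetry(rec.gaw_left, rec.gaw_right, cyc_l)
        sps, spsi_m, spsi_s = symmetry.spatial_symmetry(rec.gaw_left, rec.gaw_right, cyc_l)
        wasi = symmetry.waveform_symmetry(rec.gaw_left, rec.gaw_right, cyc_l)
        out["gaw_AmS_Mean_au"], out["gaw_AmSI_Mean_au"], out["gaw_AmSI_Std_au"] = ams, amsi_m, amsi_s
        out["gaw_SpS_Mean_au"], out["gaw_SpSI_Mean_au"], out["gaw_SpSI_Std_au"] = sps, spsi_m, spsi_s
        out["gaw_WaSI_Mean_au"] = wasi

        cyc_min = detect_cycles(rec.gaw_total, rec.fs_gaw, basis="minimum")
        pha, phai_m, phai_s = symmetry.phase_asymmetry(rec.gaw_left, rec.gaw_right, cyc_min)
        out["gaw_PhA_Mean_au"], out["gaw_PhAI_Mean_au"], out["gaw_PhAI_Std_au"] = pha, phai_m, phai_s
    except GawkitError as exc:
        pv.flags["gaw"] = str(exc)

    # ---- acoustic side --------------------------------------------------
    try:
        cyc_ac = detect_cycles(rec.acoustic, rec.fs_acoustic, basis="maximum")
        table_ac = perturb.cycle_table(rec.acoustic, cyc_ac)
        f0_mean_ac, avi = _perturbation_block(out, "ac", table_ac)
        out["ac_AVI_dB"] = avi
        ac_spectral = noise.SpectralConfig(band_max_hz=5000.0)
        _noise_block(out, "ac", rec.acoustic, rec.fs_acoustic, cyc_ac, f0_mean_ac, ac_spectral)
    except GawkitError as exc:
        pv.flags["acoustic"] = str(exc)

    return pv


def cohort_parameters(recordings) -> pd.DataFrame:
    """Extract the battery for every recording; one row per subject."""
    rows = [extract_parameters(rec).to_row() for rec in recordings]
    return pd.DataFrame(rows, columns=["subject_id", "group", *PARAMETER_COLUMNS])
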