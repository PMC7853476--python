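"""Recording container plus WAV/CSV readers and writers.

A recording is a pair of synchronized tracks from one sustained-phonation
take: the glottal area waveform (total plus left/right halves) sampled at
the video frame rate, and the microphone signal sampled at the audio rate.
On disk a recording is one mono PCM WAV file and one GAW CSV with columns
``time_s, gaw_total, gaw_left, gaw_right``; a cohort is tied together by a
manifest CSV (``subject_id, group, wav_path, gaw_csv_path``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import AlignmentError, FormatError

GROUPS = ("NF", "FDF", "NM", "FDM")
FEMALE_GROUPS = ("NF", "FDF")
MALE_GROUPS = ("NM", "FDM")

GAW_CSV_COLUMNS = ("time_s", "gaw_total", "gaw_left", "gaw_right")

#: schema version stamped into every CSV artifact header
SCHEMA_VERSION = "gawkit-1"


@dataclass
class Recording:
    """Synchronized GAW and acoustic tracks for one subject.

    Attributes
    ----------
    gaw_total, gaw_left, gaw_right : ndarray
        Glottal area series (arbitrary area units) at ``fs_gaw``.
    acoustic : ndarray
        Microphone pressure series (arbitrary units) at ``fs_acoustic``.
    fs_gaw, fs_acoustic : float
        Sampling rates in samples/s.
    subject_id, group : str
        Cohort bookkeeping; ``group`` is one of ``NF, FDF, NM, FDM``.
    """

    gaw_total: np.ndarray
    gaw_left: np.ndarray
    gaw_right: np.ndarray
    acoustic: np.ndarray
    fs_gaw: float
    fs_acoustic: float
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.gaw_total = np.asarray(self.gaw_total, dtype=float)
        self.gaw_left = np.asarray(self.gaw_left, dtype=float)
        self.gaw_right = np.asarray(self.gaw_right, dtype=float)
        self.acoustic = np.asarray(self.acoustic, dtype=float)
        if not (len(self.gaw_total) == len(self.gaw_left) == len(self.gaw_right)):
            raise AlignmentError("GAW tracks must have equal length")

    @property
    def duration_s(self) -> float:
        return len(self.gaw_total) / self.fs_gaw


def write_recording(rec: Recording, wav_path, gaw_csv_path) -> None:
    """Write the acoustic track as 16-bit PCM WAV and the GAWs as CSV."""
    wav_path = Path(wav_path)
    gaw_csv_path = Path(gaw_csv_path)
    x = rec.acoustic
    peak = np.max(np.abs(x)) if len(x) else 0.0
    scale = 0.95 / peak if peak > 0 else 1.0
    pcm = np.round(x * scale * 32767.0).astype(np.int16)
    wavfile.write(wav_path, int(rec.fs_acoustic), pcm)
    t = np.arange(len(rec.gaw_total)) / rec.fs_gaw
    df = pd.DataFrame(
        {
            "time_s": t,
            "gaw_total": rec.gaw_total,
            "gaw_left": rec.gaw_left,
            "gaw_right": rec.gaw_right,
        }
    )
    df.to_csv(gaw_csv_path, index=False)


def read_recording(
    wav_path,
    gaw_csv_path,
    subject_id: str = "",
    group: str = "",
    expected_fs_acoustic: float | None = None,
) -> Recording:
    """Load one recording from a WAV file and a GAW CSV.

    The acoustic sampling rate is taken from the WAV header; if it differs
    from ``expected_fs_acoustic`` by more than 0.1% a warning is issued and
    the file's rate wins.  The GAW rate is inferred from the CSV time column,
    which must be uniform.
    """
    wav_path = Path(wav_path)
    gaw_csv_path = Path(gaw_csv_path)
    fs_wav, data = wavfile.read(wav_path)
    if data.ndim != 1:
        raise FormatError(f"{wav_path}: expected mono WAV, got {data.shape[1]} channels")
    if np.issubdtype(data.dtype, np.integer):
        acoustic = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        acoustic = data.astype(float)
    if expected_fs_acoustic is not None and abs(fs_wav - expected_fs_acoustic) > 1e-3 * expected_fs_acoustic:
        warnings.warn(
            f"{wav_path}: sampling rate {fs_wav} differs from configured "
            f"{expected_fs_acoustic}; using the file's rate",
            stacklevel=2,
        )

    df = pd.read_csv(gaw_csv_path)
    missing = [c for c in GAW_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{gaw_csv_path}: missing columns {missing}")
    if df[list(GAW_CSV_COLUMNS)].isna().any().any():
        raise FormatError(f"{gaw_csv_path}: NaN values in GAW columns")
    t = df["time_s"].to_numpy(float)
    dt = np.diff(t)
    if len(dt) < 1 or dt.min() <= 0 or (dt.max() - dt.min()) > 1e-6 * dt.mean():
        raise FormatError(f"{gaw_csv_path}: time column is not uniformly sampled")
    fs_gaw = 1.0 / dt.mean()

    return Recording(
        gaw_total=df["gaw_total"].to_numpy(float),
        gaw_left=df["gaw_left"].to_numpy(float),
        gaw_right=df["gaw_right"].to_numpy(float),
        acoustic=acoustic,
        fs_gaw=float(np.round(fs_gaw, 6)),
        fs_acoustic=float(fs_wav),
        subject_id=subject_id,
        group=group,
    )


@dataclass
class CohortManifest:
    """Index of a cohort on disk: one row per subject."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("subject_id", "group", "wav_path", "gaw_csv_path")

    def validate(self, base_dir: Path | None = None) -> None:
        missing = [c for c in self.REQUIRED if c not in self.rows.columns]
        if missing:
            raise FormatError(f"manifest missing columns {missing}")
        if self.rows["subject_id"].duplicated().any():
            raise FormatError("manifest contains duplicate subject_ids")
        bad = set(self.rows["group"]) - set(GROUPS)
        if bad:
            raise FormatError(f"unknown group labels {sorted(bad)}")
        if base_dir is not None:
            for _, row in self.rows.iterrows():
                for col in ("wav_path", "gaw_csv_path"):
                    p = Path(base_dir) / row[col]
                    if not p.exists():
                        raise FormatError(f"manifest references missing file {p}")


def read_manifest(path) -> CohortManifest:
    path = Path(path)
    m = CohortManifest(pd.read_csv(path, comment="#"))
    m.validate(base_dir=path.parent)
    return m


def write_manifest(manifest: CohortManifest, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION}\n")
        manifest.rows.to_csv(fh, index=False)


def iter_recordings(manifest: CohortManifest, base_dir):
    """Yield Recording objects for each manifest row."""
    base_dir = Path(base_dir)
    for _, row in manifest.rows.iterrows():
        yield read_recording(
            base_dir / row["wav_path"],
            base_dir / row["gaw_csv_path"],
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
        )


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a CSV artifact with the schema-version header comment."""
    with open(path, "w") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION}\n")
        df.to_csv(fh, index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)
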