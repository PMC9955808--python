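"""Reading and writing of stretch-session recordings and feature tables.

A session is stored as two CSV files, one per sample rate:

* low-rate table (1000 Hz): ``time_s,angle_x_deg,angle_y_deg,force_n``
* high-rate table (2000 Hz): ``time_s,semg_mv``

UTF-8, "." decimal separator, no thousands separators.  Times are stored
explicitly (rather than inferred from the nominal rate) so that files with
dropped samples are detectable.  Feature tables carry identifier columns
followed by the 17 canonical feature names (see :mod:`masgrade.features`).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

#: The six ordered grades of the Modified Ashworth Scale.
MAS_LABELS: tuple[str, ...] = ("0", "1", "1+", "2", "3", "4")

#: Nominal sample rates of the two acquisition streams (Hz).
FS_LOW = 1000.0
FS_HIGH = 2000.0

LOW_RATE_COLUMNS = ["time_s", "angle_x_deg", "angle_y_deg", "force_n"]
HIGH_RATE_COLUMNS = ["time_s", "semg_mv"]

#: Identifier columns of a feature table, in canonical order.
META_COLUMNS = ["subject_id", "trial_id", "stretch_index", "speed", "mas_label"]


class FormatError(ValueError):
    """Raised when a file violates the recording or feature-table schema."""


@dataclasses.dataclass
class StretchRecording:
    """One raw passive elbow-stretch session.

    The goniometer and myometer channels share the 1000 Hz timebase
    (``time_lo``); the surface EMG is sampled at 2000 Hz (``time_hi``).
    """

    subject_id: str
    trial_id: str
    time_lo: np.ndarray
    angle_x: np.ndarray  # deg
    angle_y: np.ndarray  # deg
    force: np.ndarray  # N
    time_hi: np.ndarray
    semg: np.ndarray  # mV
    mas_label: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("time_lo", "angle_x", "angle_y", "force", "time_hi", "semg"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    def validate(self) -> None:
        n = len(self.time_lo)
        for name in ("angle_x", "angle_y", "force"):
            if len(getattr(self, name)) != n:
                raise FormatError(
                    f"channel '{name}' has {len(getattr(self, name))} samples, "
                    f"expected {n} (length of time_s)"
                )
        if n == 0 or len(self.semg) == 0:
            raise FormatError("zero-length channel: recordings must be non-empty")
        if len(self.semg) != len(self.time_hi):
            raise FormatError(
                f"channel 'semg' has {len(self.semg)} samples, expected "
                f"{len(self.time_hi)} (length of time_s)"
            )
        for name in ("time_lo", "time_hi"):
            t = getattr(self, name)
            if np.any(np.diff(t) <= 0):
                raise FormatError(f"time vector '{name}' is not strictly increasing")
            if abs(t[0]) > 1e-9:
                raise FormatError(f"time vector '{name}' does not start at 0")
        if self.mas_label is not None and self.mas_label not in MAS_LABELS:
            raise FormatError(
                f"mas_label {self.mas_label!r} not one of {MAS_LABELS}"
            )

    @property
    def n_low(self) -> int:
        return len(self.time_lo)

    @property
    def n_high(self) -> int:
        return len(self.time_hi)


def _read_csv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in columns:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column '{col}'")
    extra = [c for c in df.columns if c not in columns and c != "mas_label"]
    if extra:
        raise FormatError(f"{path}: unexpected column(s) {extra}")
    return df


def read_recording(
    path_lo: str | Path,
    path_hi: str | Path,
    subject_id: str = "",
    trial_id: str = "",
) -> StretchRecording:
    """Read one session from its low-rate and high-rate CSV files.

    The low-rate file may carry a constant ``mas_label`` column; it is
    recovered as the recording's label.
    """
    lo = _read_csv(path_lo, LOW_RATE_COLUMNS)
    hi = _read_csv(path_hi, HIGH_RATE_COLUMNS)
    mas_label = None
    if "mas_label" in lo.columns:
        labels = lo["mas_label"].astype(str).unique()
        if len(labels) != 1:
            raise FormatError(f"{path_lo}: non-constant mas_label column")
        mas_label = labels[0]
    return StretchRecording(
        subject_id=subject_id,
        trial_id=trial_id,
        time_lo=lo["time_s"].to_numpy(),
        angle_x=lo["angle_x_deg"].to_numpy(),
        angle_y=lo["angle_y_deg"].to_numpy(),
        force=lo["force_n"].to_numpy(),
        time_hi=hi["time_s"].to_numpy(),
        semg=hi["semg_mv"].to_numpy(),
        mas_label=mas_label,
    )


def write_recording(
    rec: StretchRecording, path_lo: str | Path, path_hi: str | Path
) -> None:
    """Write a session to the two-file CSV dialect (lossless round trip)."""
    rec.validate()
    lo = pd.DataFrame(
        {
            "time_s": rec.time_lo,
            "angle_x_deg": rec.angle_x,
            "angle_y_deg": rec.angle_y,
            "force_n": rec.force,
        }
    )
    if rec.mas_label is not None:
        lo["mas_label"] = rec.mas_label
    hi = pd.DataFrame({"time_s": rec.time_hi, "semg_mv": rec.semg})
    # repr-precision floats keep the round trip below 1e-9
    lo.to_csv(path_lo, index=False, float_format="%.12g")
    hi.to_csv(path_hi, index=False, float_format="%.12g")


def feature_table_columns() -> list[str]:
    """Canonical column order of a feature CSV."""
    from masgrade.features import FEATURE_NAMES

    return META_COLUMNS + list(FEATURE_NAMES)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature CSV; ``mas_label`` may be absent (prediction mode)."""
    df = pd.read_csv(path, dtype={"subject_id": str, "trial_id": str})
    cols = feature_table_columns()
    required = [c for c in cols if c != "mas_label"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column '{col}'")
    allowed = set(cols)
    unknown = [c for c in df.columns if c not in allowed]
    if unknown:
        raise FormatError(f"{path}: unknown feature column(s) {unknown}")
    if "mas_label" in df.columns:
        df["mas_label"] = df["mas_label"].astype(str)
        bad = set(df["mas_label"]) - set(MAS_LABELS)
        if bad:
            raise FormatError(f"{path}: invalid mas_label value(s) {sorted(bad)}")
        order = cols
    else:
        order = [c for c in cols if c != "mas_label"]
    return df[order]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table in canonical column order."""
    cols = feature_table_columns()
    if "mas_label" not in table.columns:
        cols = [c for c in cols if c != "mas_label"]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise FormatError(f"feature table missing column(s) {missing}")
    unknown = [c for c in table.columns if c not in cols]
    if unknown:
        raise FormatError(f"unknown feature column(s) {unknown}")
    table[cols].to_csv(path, index=False, float_format="%.12g")
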