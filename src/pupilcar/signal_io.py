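"""Plain-text I/O for physiological signals, pupillometry records and cohorts.

Signals are stored as CSV with a ``#``-prefixed metadata header::

    # label=ABP units=mmHg rate_hz=50 format=%.6g
    time_s,value
    0.000000,80.1
    ...

Times are seconds from recording start (0-based). Missing samples are
written as an empty value field and represented internally as NaN. No
imputation happens at the I/O layer.

Cohort tables are one row per patient with per-eye pupillometry columns,
a group label (``septic`` / ``non_septic``) and relative paths to the two
signal files. Rows violating pupillometry range invariants are rejected
with reasons collected, never silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

VALID_LABELS = ("ABP", "FV")
VALID_GROUPS = ("septic", "non_septic")
UNITS = {"ABP": "mmHg", "FV": "cm/s"}

#: sampling rates (Hz) conformant with the study protocol
STUDY_RATE_RANGE = (50.0, 100.0)

#: decimal formatting used by write_signal, stated in the file header
WRITE_FORMAT = "%.6g"


class SignalIOError(Exception):
    """Malformed signal file (parse failure)."""


class ValidationError(ValueError):
    """Input violates a domain invariant."""


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled physiological time series.

    Parameters
    ----------
    times : np.ndarray
        Seconds from recording start, strictly increasing, uniform spacing.
    values : np.ndarray
        mmHg for ABP, cm/s for FV. NaN marks a missing sample.
    rate : float
        Sampling frequency in Hz (spacing is 1/rate).
    label : str
        One of ``ABP`` or ``FV``.
    """

    times: np.ndarray
    values: np.ndarray
    rate: float
    label: str

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if self.label not in VALID_LABELS:
            raise ValidationError(f"unknown signal label {self.label!r}")
        if times.ndim != 1 or values.ndim != 1 or len(times) != len(values):
            raise ValidationError("times and values must be 1-D of equal length")
        if len(times) == 0:
            raise ValidationError("empty signal")
        if self.rate <= 0:
            raise ValidationError("rate must be positive")
        if len(times) > 1:
            dt = np.diff(times)
            if np.any(dt <= 0):
                raise ValidationError("times must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.rate)) > 1e-9:
                raise ValidationError(
                    "non-uniform sampling: spacing deviates from 1/rate by > 1e-9 s"
                )
        if not np.all(np.isfinite(values) | np.isnan(values)):
            raise ValidationError("values must be finite or NaN (missing)")

    @property
    def duration_s(self) -> float:
        """Time span covered, including the final sample interval."""
        return len(self.times) / self.rate

    @property
    def study_conformant_rate(self) -> bool:
        """Whether the sampling rate lies in the 50-100 Hz protocol range."""
        lo, hi = STUDY_RATE_RANGE
        return lo <= self.rate <= hi

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class EyeReading:
    """One eye's automated-pupillometry measurement.

    npi is the device's 0-5 Neurological Pupil Index; size_mm the baseline
    pupil diameter; constriction_pct the % reduction from baseline after
    the calibrated light stimulus; cv_mm_s the constriction velocity;
    latency_s the constriction onset latency.
    """

    npi: float
    size_mm: float
    constriction_pct: float
    cv_mm_s: float
    latency_s: float

    def validate(self) -> list[str]:
        """Return a list of invariant-violation reasons (empty if valid)."""
        reasons = []
        if not 0.0 <= self.npi <= 5.0:
            reasons.append("npi out of range")
        if not self.size_mm > 0:
            reasons.append("size_mm not positive")
        if not 0.0 <= self.constriction_pct <= 100.0:
            reasons.append("constriction_pct out of range")
        if self.cv_mm_s < 0:
            reasons.append("cv_mm_s negative")
        if self.latency_s < 0:
            reasons.append("latency_s negative")
        return reasons


@dataclass
class PatientRecord:
    """One patient's paired signals, pupillometry and group label.

    Signals may be unloaded stubs: ``abp``/``fv`` hold None while
    ``abp_file``/``fv_file`` carry the paths; load_signals() fills them in.
    At least one eye must be present.
    """

    patient_id: str
    group: str
    left_eye: Optional[EyeReading] = None
    right_eye: Optional[EyeReading] = None
    abp: Optional[Signal] = None
    fv: Optional[Signal] = None
    abp_file: Optional[str] = None
    fv_file: Optional[str] = None

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValidationError(f"unknown group label {self.group!r}")
        if self.left_eye is None and self.right_eye is None:
            raise ValidationError("at least one eye must be present")

    def load_signals(self, base_dir: Path | str = ".") -> "PatientRecord":
        """Load the referenced signal files; errors surface here, not at
        cohort-table parse time."""
        base = Path(base_dir)
        abp = self.abp if self.abp is not None else read_signal(base / self.abp_file, "ABP")
        fv = self.fv if self.fv is not None else read_signal(base / self.fv_file, "FV")
        return replace(self, abp=abp, fv=fv)


# ---------------------------------------------------------------------------
# signal CSV
# ---------------------------------------------------------------------------

def write_signal(signal: Signal, path: Path | str) -> None:
    """Write a Signal as a CSV with metadata header.

    Formatting is deterministic: 6 significant digits (stated in the
    header). Missing samples are written as an empty value field.
    """
    path = Path(path)
    units = UNITS[signal.label]
    with open(path, "w") as fh:
        fh.write(
            f"# label={signal.label} units={units} "
            f"rate_hz={signal.rate:g} format={WRITE_FORMAT}\n"
        )
        fh.write("time_s,value\n")
        for t, v in zip(signal.times, signal.values):
            vs = "" if math.isnan(v) else (WRITE_FORMAT % v)
            fh.write(f"{WRITE_FORMAT % t},{vs}\n")


def read_signal(path: Path | str, label: str) -> Signal:
    """Read a signal CSV written by write_signal (or hand-authored).

    The sampling rate is inferred from the median time step; a rate_hz
    metadata line, when present, is cross-checked but the inferred rate
    wins for single-row files it cannot be inferred from.
    """
    path = Path(path)
    if label not in VALID_LABELS:
        raise ValidationError(f"unknown signal label {label!r}")
    header_rate: Optional[float] = None
    times: list[float] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("rate_hz="):
                        header_rate = float(tok.split("=", 1)[1])
                continue
            if line.startswith("time_s"):
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise SignalIOError(f"{path}: malformed row at line {lineno}: {raw!r}")
            try:
                t = float(parts[0])
            except ValueError as exc:
                raise SignalIOError(
                    f"{path}: unparseable time at line {lineno}: {raw!r}"
                ) from exc
            if parts[1] == "":
                v = math.nan
            else:
                try:
                    v = float(parts[1])
                except ValueError as exc:
                    raise SignalIOError(
                        f"{path}: unparseable value at line {lineno}: {raw!r}"
                    ) from exc
            times.append(t)
            values.append(v)
    if not times:
        raise SignalIOError(f"{path}: no data rows")
    t_arr = np.asarray(times)
    if len(t_arr) > 1:
        dt = np.diff(t_arr)
        if np.any(dt <= 0):
            raise ValidationError(f"{path}: time column not strictly increasing")
        rate = 1.0 / float(np.median(dt))
    elif header_rate is not None:
        rate = header_rate
    else:
        raise ValidationError(f"{path}: cannot infer rate from a single sample")
    return Signal(times=t_arr, values=np.asarray(values), rate=rate, label=label)


# ---------------------------------------------------------------------------
# cohort CSV
# ---------------------------------------------------------------------------

_EYE_FIELDS = ("npi", "size_mm", "constriction_pct", "cv_mm_s", "latency_s")

COHORT_COLUMNS = (
    ["patient_id", "group"]
    + [f"{side}_{f}" for side in ("left", "right") for f in _EYE_FIELDS]
    + ["abp_file", "fv_file"]
)


def _parse_eye(row: pd.Series, side: str) -> Optional[EyeReading]:
    vals = {f: row.get(f"{side}_{f}") for f in _EYE_FIELDS}
    if all(pd.isna(v) for v in vals.values()):
        return None
    if any(pd.isna(v) for v in vals.values()):
        raise ValidationError(f"{side} eye partially missing")
    return EyeReading(**{k: float(v) for k, v in vals.items()})


def read_cohort(path: Path | str) -> tuple[list[PatientRecord], list[dict]]:
    """Read a cohort table into PatientRecord stubs (signals unloaded).

    Returns (accepted_records, rejected_rows); each rejected row is a dict
    with patient_id and the list of reasons. records_in is always
    len(accepted) + len(rejected). Signal files referenced by a row are
    NOT opened here; a bad path fails later at load_signals().
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing_cols = set(COHORT_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValidationError(f"cohort table missing columns: {sorted(missing_cols)}")
    accepted: list[PatientRecord] = []
    rejected: list[dict] = []
    for _, row in df.iterrows():
        reasons: list[str] = []
        pid = str(row["patient_id"])
        group = str(row["group"])
        if group not in VALID_GROUPS:
            raise ValidationError(f"unknown group label {group!r} (patient {pid})")
        eyes: dict[str, Optional[EyeReading]] = {}
        for side in ("left", "right"):
            try:
                eye = _parse_eye(row, side)
            except ValidationError as exc:
                reasons.append(str(exc))
                eye = None
            if eye is not None:
                bad = eye.validate()
                if bad:
                    reasons.extend(bad)
                    eye = None
            eyes[side] = eye
        if eyes["left"] is None and eyes["right"] is None and not reasons:
            reasons.append("no eye present")
        if reasons:
            rejected.append({"patient_id": pid, "reasons": reasons})
            continue
        accepted.append(
            PatientRecord(
                patient_id=pid,
                group=group,
                left_eye=eyes["left"],
                right_eye=eyes["right"],
                abp_file=str(row["abp_file"]),
                fv_file=str(row["fv_file"]),
            )
        )
    return accepted, rejected


def write_cohort(records: list[PatientRecord], path: Path | str) -> None:
    """Write PatientRecord stubs as a cohort CSV (inverse of read_cohort)."""
    rows = []
    for rec in records:
        row: dict = {"patient_id": rec.patient_id, "group": rec.group}
        for side in ("left", "right"):
            eye = getattr(rec, f"{side}_eye")
            for f in _EYE_FIELDS:
                row[f"{side}_{f}"] = getattr(eye, f) if eye is not None else np.nan
        row["abp_file"] = rec.abp_file
        row["fv_file"] = rec.fv_file
        rows.append(row)
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)
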