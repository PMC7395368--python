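"""Per-patient aggregation of two-eye pupillometry readings.

The analysis uses the median across both eyes for every variable (for two
eyes the median is the arithmetic midpoint), a "worst NPI" defined as the
minimum Neurological Pupil Index across available eyes, and the
conventional NPI cut-off: > 3 normal, 0-3 abnormal (the boundary value 3
is abnormal). When only one eye was measured it is used verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .signal_io import EyeReading, ValidationError


@dataclass(frozen=True)
class PupilMeasures:
    """Patient-level pupillometry: two-eye medians plus the worst NPI."""

    mean_npi: float
    worst_npi: float
    size_mm: float
    constriction_pct: float
    cv_mm_s: float
    latency_s: float
    npi_status: str  # "normal" | "abnormal"


def npi_status(npi: float) -> str:
    """Classify an NPI value: normal iff NPI > 3 (3 itself is abnormal)."""
    if not 0.0 <= npi <= 5.0:
        raise ValidationError("npi must lie in [0, 5]")
    return "normal" if npi > 3.0 else "abnormal"


def aggregate_eyes(
    left: Optional[EyeReading], right: Optional[EyeReading]
) -> PupilMeasures:
    """Combine per-eye readings into the patient-level variables.

    Symmetric in its arguments; with one eye absent the present eye's
    values are used verbatim. worst_npi <= mean_npi always.
    """
    eyes = [e for e in (left, right) if e is not None]
    if not eyes:
        raise ValidationError("at least one eye must be present")

    def med(attr: str) -> float:
        vals = [getattr(e, attr) for e in eyes]
        return float(sum(vals)) / len(vals)

    mean_npi = med("npi")
    worst_npi = min(e.npi for e in eyes)
    return PupilMeasures(
        mean_npi=mean_npi,
        worst_npi=worst_npi,
        size_mm=med("size_mm"),
        constriction_pct=med("constriction_pct"),
        cv_mm_s=med("cv_mm_s"),
        latency_s=med("latency_s"),
        npi_status=npi_status(mean_npi),
    )
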