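"""End-to-end study orchestration.

Runs the full analysis on a cohort: per-patient Mxa and autoregulation
status, pupillometry aggregation, group summaries (median/IQR, altered-CAR
percentages, septic vs non-septic comparisons), the Mxa-vs-pupillometry
correlation matrix (r^2 and p per variable, overall and within groups),
impaired-vs-intact rank-sum comparisons, and ROC analyses of the mean NPI
against impaired autoregulation. Results are emitted as CSV tables plus a
single JSON summary at full precision.

No multivariable adjustment and no multiple-testing correction are
performed; the JSON carries an explicit caveat flag instead.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import stats as st
from .mxa import MxaConfig, UnusableRecordingError, compute_mxa
from .pupillometry import aggregate_eyes
from .signal_io import PatientRecord, ValidationError

#: pupillometry variables correlated with Mxa, in display order
PUPIL_VARS = (
    "mean_npi",
    "size_mm",
    "constriction_pct",
    "cv_mm_s",
    "latency_s",
    "worst_npi",
)
STRATA = ("all", "septic", "non_septic")

#: analyses with fewer subjects than this per cell are flagged
MIN_CELL_N = 10


@dataclass
class StudyResult:
    per_patient: pd.DataFrame
    summary: pd.DataFrame          # Table-1-style: median/IQR or % per group + p
    correlations: pd.DataFrame     # Table-2-style: r2/p per variable x stratum
    comparisons: pd.DataFrame      # impaired vs intact rank-sum per variable x stratum
    roc: dict                      # stratum -> RocResult-as-dict or {"flag": ...}
    excluded: list = field(default_factory=list)
    caveats: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


def _stratum_mask(df: pd.DataFrame, stratum: str) -> pd.Series:
    return df["group"] == stratum if stratum != "all" else pd.Series(True, index=df.index)


def run_study(
    cohort: list[PatientRecord],
    mxa_config: Optional[MxaConfig] = None,
    signals_dir: Path | str = ".",
) -> StudyResult:
    """Run the whole analysis on a cohort of patient records.

    Patients whose recordings cannot yield an Mxa are excluded listwise
    (with logged reasons) from Mxa-dependent analyses. Requires at least
    one analyzable patient; strata with a single autoregulation class are
    flagged rather than crashed.
    """
    if mxa_config is None:
        mxa_config = MxaConfig()
    rows = []
    excluded = []
    for rec in cohort:
        try:
            if rec.abp is None or rec.fv is None:
                rec = rec.load_signals(signals_dir)
            res = compute_mxa(rec.abp, rec.fv, mxa_config)
        except (UnusableRecordingError, ValidationError, OSError) as exc:
            excluded.append({"patient_id": rec.patient_id, "reason": str(exc)})
            continue
        pupils = aggregate_eyes(rec.left_eye, rec.right_eye)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "group": rec.group,
                "mxa": res.mxa,
                "car_status": res.car_status,
                "n_windows": res.n_windows,
                "mean_npi": pupils.mean_npi,
                "worst_npi": pupils.worst_npi,
                "size_mm": pupils.size_mm,
                "constriction_pct": pupils.constriction_pct,
                "cv_mm_s": pupils.cv_mm_s,
                "latency_s": pupils.latency_s,
                "npi_status": pupils.npi_status,
            }
        )
    if not rows:
        raise ValidationError("no analyzable patients in cohort")
    df = pd.DataFrame(rows)
    caveats = ["no multivariable adjustment or multiple-testing correction applied"]

    summary = _summary_table(df, caveats)
    correlations = _correlation_table(df, caveats)
    comparisons = _comparison_table(df, caveats)
    roc = _roc_analyses(df, caveats)

    cohort_hash = hashlib.sha256(
        df.sort_values("patient_id").to_csv(index=False).encode()
    ).hexdigest()[:16]
    meta = {
        "n_patients": int(len(df)),
        "n_excluded": len(excluded),
        "n_septic": int((df["group"] == "septic").sum()),
        "n_nonseptic": int((df["group"] == "non_septic").sum()),
        "mxa_config": {
            "window_s": mxa_config.window_s,
            "overlap_frac": mxa_config.overlap_frac,
            "impaired_threshold": mxa_config.impaired_threshold,
        },
        "cohort_hash": cohort_hash,
    }
    return StudyResult(
        per_patient=df,
        summary=summary,
        correlations=correlations,
        comparisons=comparisons,
        roc=roc,
        excluded=excluded,
        caveats=caveats,
        metadata=meta,
    )


def _summary_table(df: pd.DataFrame, caveats: list) -> pd.DataFrame:
    """Per-group medians/IQRs and altered-CAR percentages with septic vs
    non-septic comparison p-values."""
    rows = []
    septic = df[df["group"] == "septic"]
    nonseptic = df[df["group"] == "non_septic"]
    for var in ("mxa",) + PUPIL_VARS:
        row = {"variable": var, "kind": "median_iqr"}
        for stratum in STRATA:
            sub = df[_stratum_mask(df, stratum)]
            if len(sub):
                med, q25, q75 = st.median_iqr(sub[var].to_numpy())
                row[f"{stratum}_median"] = med
                row[f"{stratum}_q25"] = q25
                row[f"{stratum}_q75"] = q75
        if len(septic) and len(nonseptic):
            _, p = st.wilcoxon_rank_sum(septic[var].to_numpy(), nonseptic[var].to_numpy())
            row["p_septic_vs_nonseptic"] = p
        rows.append(row)
    row = {"variable": "altered_car", "kind": "percentage"}
    for stratum in STRATA:
        sub = df[_stratum_mask(df, stratum)]
        if len(sub):
            n_imp = int((sub["car_status"] == "impaired").sum())
            row[f"{stratum}_median"] = st.proportion_pct(n_imp, len(sub))
            row[f"{stratum}_count"] = n_imp
            row[f"{stratum}_total"] = len(sub)
    rows.append(row)
    out = pd.DataFrame(rows)
    if min(len(septic), len(nonseptic)) < MIN_CELL_N:
        caveats.append("a group has fewer than 10 patients; comparisons unreliable")
    return out


def _correlation_table(df: pd.DataFrame, caveats: list) -> pd.DataFrame:
    """Pearson r^2/p of Mxa against each pupillometry variable, per stratum."""
    rows = []
    for var in PUPIL_VARS:
        row: dict = {"variable": var}
        for stratum in STRATA:
            sub = df[_stratum_mask(df, stratum)]
            if len(sub) >= 3 and np.ptp(sub[var]) > 0 and np.ptp(sub["mxa"]) > 0:
                res = st.pearson_test(sub["mxa"].to_numpy(), sub[var].to_numpy())
                row[f"{stratum}_r"] = res.r
                row[f"{stratum}_r2"] = res.r_squared
                row[f"{stratum}_p"] = res.p_two_sided
                row[f"{stratum}_n"] = res.n
            else:
                caveats.append(f"correlation {var}/{stratum} not computable")
        rows.append(row)
    return pd.DataFrame(rows)


def _comparison_table(df: pd.DataFrame, caveats: list) -> pd.DataFrame:
    """Rank-sum comparison of each pupillometry variable between impaired
    and intact autoregulation, overall and within groups."""
    rows = []
    for var in PUPIL_VARS:
        row: dict = {"variable": var}
        for stratum in STRATA:
            sub = df[_stratum_mask(df, stratum)]
            imp = sub[sub["car_status"] == "impaired"][var].to_numpy()
            okay = sub[sub["car_status"] == "intact"][var].to_numpy()
            if len(imp) and len(okay):
                _, p = st.wilcoxon_rank_sum(imp, okay)
                row[f"{stratum}_p"] = p
                row[f"{stratum}_median_impaired"] = float(np.median(imp))
                row[f"{stratum}_median_intact"] = float(np.median(okay))
                if min(len(imp), len(okay)) < MIN_CELL_N:
                    caveats.append(f"comparison {var}/{stratum}: a cell has n < 10")
            else:
                caveats.append(f"comparison {var}/{stratum}: single-class stratum")
        rows.append(row)
    return pd.DataFrame(rows)


def _roc_analyses(df: pd.DataFrame, caveats: list) -> dict:
    """ROC of the mean NPI against impaired autoregulation per stratum;
    single-class strata are flagged, never crashed."""
    out = {}
    for stratum in STRATA:
        sub = df[_stratum_mask(df, stratum)]
        labels = (sub["car_status"] == "impaired").to_numpy()
        if len(sub) == 0 or labels.all() or not labels.any():
            out[stratum] = {"flag": "single-class labels; ROC undefined"}
            caveats.append(f"roc/{stratum}: single-class labels")
            continue
        res = st.roc_auc(sub["mean_npi"].to_numpy(), labels)
        out[stratum] = {
            "auc": res.auc,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "sensitivity": res.sensitivity,
            "specificity": res.specificity,
            "threshold": res.threshold,
            "direction": res.direction,
            "n": int(len(sub)),
        }
    return out


# display rounding: Mxa and r^2 to 2 decimals, percentages to 1 decimal,
# p-values to 3 significant digits (full precision lives in the JSON)
def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0 or not np.isfinite(x):
        return x
    return float(np.format_float_positional(x, precision=sig, fractional=False))


def render_tables(result: StudyResult, out_dir: Path | str) -> dict[str, Path]:
    """Write the study tables as CSV plus one full-precision JSON summary.

    Output is deterministic (byte-identical for identical input). The CSVs
    apply the display rounding; summary.json keeps full precision.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    per_patient = result.per_patient.copy()
    paths["per_patient"] = out / "per_patient.csv"
    per_patient.to_csv(paths["per_patient"], index=False)

    def fmt(df: pd.DataFrame) -> pd.DataFrame:
        d = df.copy()
        for c in d.columns:
            if c.endswith(("_p", "p_septic_vs_nonseptic")):
                d[c] = d[c].map(lambda v: _round_sig(v) if pd.notna(v) else v)
            elif d[c].dtype.kind == "f":
                d[c] = d[c].round(2)
        return d

    for name, table in (
        ("summary", result.summary),
        ("correlations", result.correlations),
        ("comparisons", result.comparisons),
    ):
        paths[name] = out / f"{name}.csv"
        fmt(table).to_csv(paths[name], index=False)

    payload = {
        "metadata": result.metadata,
        "summary": result.summary.to_dict(orient="records"),
        "correlations": result.correlations.to_dict(orient="records"),
        "comparisons": result.comparisons.to_dict(orient="records"),
        "roc": result.roc,
        "excluded": result.excluded,
        "caveats": sorted(set(result.caveats)),
    }
    paths["json"] = out / "summary.json"
    with open(paths["json"], "w") as fh:
        json.dump(payload, fh, indent=1, allow_nan=True, sort_keys=True)

    # figure data: per-group NPI quantiles by autoregulation status and the
    # Mxa/NPI scatter pairs (plotting itself is left to the caller)
    fig_rows = []
    for stratum in STRATA:
        sub = result.per_patient[_stratum_mask(result.per_patient, stratum)]
        for status in ("impaired", "intact"):
            vals = sub[sub["car_status"] == status]["mean_npi"].to_numpy()
            if len(vals):
                med, q25, q75 = st.median_iqr(vals)
                fig_rows.append(
                    {
                        "stratum": stratum,
                        "car_status": status,
                        "n": len(vals),
                        "npi_median": med,
                        "npi_q25": q25,
                        "npi_q75": q75,
                    }
                )
    paths["figure_data"] = out / "npi_by_car_status.csv"
    pd.DataFrame(fig_rows).to_csv(paths["figure_data"], index=False)
    return paths
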