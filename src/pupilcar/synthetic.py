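"""Synthetic ABP/FV waveforms and pupillometry cohorts with known ground truth.

The clinical recordings behind the Mxa/pupillometry analysis were never
deposited, so this module emulates all three inputs:

* **ABP**: mean pressure plus a slow-wave component (sum of sinusoids at
  random frequencies in 0.005-0.05 Hz plus a 0.1 Hz component — the band
  Mxa-type indices operate on), a small ~1 Hz cardiac sinusoid, and white
  noise.
* **FV**: a mixture ``baseline + scale*[w*Z + (1-w)*E] + noise`` where Z is
  the standardized slow-wave component shared with the ABP, E an
  independent surrogate with matched spectrum, and w the pressure-passivity
  weight: w=1 is fully pressure-passive (impaired autoregulation), w=0
  fully buffered. A second-order Tiecks-Lassen state model (ARI 0-9) is
  provided as an optional physiological alternative.
* **Pupillometry**: a Neurological Pupil Index with a tunable
  population-level squared correlation to Mxa (negative slope by default:
  impaired autoregulation trends to lower NPI), plus pupil size,
  constriction, constriction velocity and latency drawn independently of
  Mxa, all calibrated to published critical-care medians/IQRs.

Cohort generation samples per-patient passivity so that the computed Mxa
distribution approximates a target median/IQR, by inverting a
pilot-simulated w -> E[Mxa] map. All generators are pure functions of
(config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import stats as sps

from .mxa import MxaConfig, compute_mxa
from .signal_io import (
    EyeReading,
    PatientRecord,
    Signal,
    ValidationError,
    write_cohort,
    write_signal,
)

# slow-wave band: fluctuations that survive 10-s averaging
SLOW_BAND_HZ = (0.005, 0.05)
SLOW_EXTRA_HZ = 0.1  # deliberately attenuated by the averaging stage
N_SLOW_COMPONENTS = 24
CARDIAC_HZ = 1.0

# cut-off separating the slow band from cardiac/noise when extracting the
# shared component of an ABP recording
SLOW_CUTOFF_HZ = 0.15


@dataclass(frozen=True)
class SimConfig:
    """Cohort-simulation settings, calibrated to the studied ICU population.

    Defaults: 52 septic / 40 non-septic patients, 480 s (8 min) recordings
    at 50 Hz, target Mxa distribution median 0.33 with SD 0.356 (matching a
    0.09-0.57 interquartile range), NPI centered at 4.33, NPI-Mxa squared
    correlation 0.04 per group with a negative slope.
    """

    n_septic: int = 52
    n_nonseptic: int = 40
    duration_s: float = 480.0
    rate_hz: float = 50.0
    mean_abp_mmhg: float = 77.0
    fv_baseline_cm_s: float = 60.0
    #: fixed pressure-passivity for every patient; None -> sample from the
    #: target Mxa distribution via the calibrated w -> E[Mxa] map
    passivity_w: Optional[float] = None
    mxa_pop_median: float = 0.33
    mxa_pop_sd: float = 0.356
    r2_target: float = 0.04
    slope_sign: int = -1
    npi_center: float = 4.33
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_septic < 0 or self.n_nonseptic < 0:
            raise ValidationError("patient counts must be >= 0")
        if self.duration_s <= 60:
            raise ValidationError("duration_s must exceed 60 s")
        if not 0.0 <= self.r2_target < 1.0:
            raise ValidationError("r2_target must be in [0, 1)")
        if not -1.0 < self.mxa_pop_median < 1.0:
            raise ValidationError("target Mxa median must lie in (-1, 1)")


@dataclass(frozen=True)
class GroundTruth:
    """Per-patient generating parameters, stored for recovery tests."""

    patient_ids: list[str]
    passivity_w: np.ndarray
    intended_mxa: np.ndarray
    computed_mxa: np.ndarray
    npi_residual: np.ndarray
    intended_car: list[str]  # "impaired" | "intact" from computed Mxa

    def __len__(self) -> int:
        return len(self.patient_ids)


# ---------------------------------------------------------------------------
# waveform generators
# ---------------------------------------------------------------------------

def generate_abp(
    duration_s: float = 480.0,
    rate_hz: float = 50.0,
    mean_mmhg: float = 77.0,
    seed: int | np.random.SeedSequence = 0,
    slow_rms_mmhg: float = 5.0,
    cardiac_amp_mmhg: float = 2.0,
    noise_sd_mmhg: float = 0.5,
) -> Signal:
    """Synthetic arterial-blood-pressure recording.

    ABP(t) = mean + S(t) + cardiac sinusoid + white noise, with S(t) a sum
    of sinusoids with random phases at N_SLOW_COMPONENTS frequencies drawn
    in 0.005-0.05 Hz plus a 0.1 Hz component, normalized to the requested
    RMS. Deterministic for a given seed.
    """
    if duration_s <= 0:
        raise ValidationError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz

    # stratified frequency draw: one component per equal sub-band, so every
    # realization covers the whole slow band (a lumpy all-low-frequency draw
    # would leave too few independent fluctuations in an 8-min recording)
    edges = np.linspace(*SLOW_BAND_HZ, N_SLOW_COMPONENTS + 1)
    freqs = np.concatenate(
        [rng.uniform(edges[:-1], edges[1:]), [SLOW_EXTRA_HZ]]
    )
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(freqs))
    amps = rng.uniform(0.5, 1.0, size=len(freqs))
    slow = (amps[:, None] * np.sin(2.0 * np.pi * freqs[:, None] * t + phases[:, None])).sum(axis=0)
    rms = np.sqrt(np.mean(slow**2))
    if slow_rms_mmhg > 0 and rms > 0:
        slow *= slow_rms_mmhg / rms
    else:
        slow[:] = 0.0

    cardiac = cardiac_amp_mmhg * np.sin(
        2.0 * np.pi * CARDIAC_HZ * t + rng.uniform(0.0, 2.0 * np.pi)
    )
    noise = noise_sd_mmhg * rng.standard_normal(n) if noise_sd_mmhg > 0 else 0.0
    values = mean_mmhg + slow + cardiac + noise
    return Signal(times=t, values=values, rate=rate_hz, label="ABP")


def slow_component(signal: Signal) -> np.ndarray:
    """Extract the demeaned slow-wave component (< SLOW_CUTOFF_HZ) of a
    signal by brick-wall Fourier filtering."""
    v = signal.values - np.mean(signal.values)
    spec = np.fft.rfft(v)
    f = np.fft.rfftfreq(len(v), d=1.0 / signal.rate)
    spec[f > SLOW_CUTOFF_HZ] = 0.0
    return np.fft.irfft(spec, n=len(v))


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    if sd == 0:
        raise ValidationError("cannot standardize a constant component")
    return (x - np.mean(x)) / sd


def _matched_spectrum_surrogate(z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent process with z's amplitude spectrum: phase randomization."""
    spec = np.fft.rfft(z)
    amp = np.abs(spec)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(spec))
    phases[0] = 0.0
    surrogate = np.fft.irfft(amp * np.exp(1j * phases), n=len(z))
    return _standardize(surrogate)


def generate_fv(
    abp: Signal,
    passivity_w: float,
    baseline_cm_s: float = 60.0,
    seed: int | np.random.SeedSequence = 0,
    fluct_rms_cm_s: float = 3.0,
    noise_sd_cm_s: float = 0.5,
) -> Signal:
    """Flow-velocity recording with tunable pressure passivity.

    FV = baseline + scale*[w*Z + (1-w)*E] + noise, where Z is the
    standardized slow-wave component of the ABP and E an independent
    surrogate with matched spectrum and unit variance. w=1 yields a fully
    pressure-passive FV (downstream Mxa -> 1); w=0 a fully buffered one
    (Mxa ~ 0 on average).
    """
    if not 0.0 <= passivity_w <= 1.0:
        raise ValidationError("passivity_w must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    z = _standardize(slow_component(abp))
    e = _matched_spectrum_surrogate(z, rng)
    mix = passivity_w * z + (1.0 - passivity_w) * e
    noise = noise_sd_cm_s * rng.standard_normal(len(z)) if noise_sd_cm_s > 0 else 0.0
    values = baseline_cm_s + fluct_rms_cm_s * mix + noise
    return Signal(times=abp.times.copy(), values=values, rate=abp.rate, label="FV")


# second-order dynamic autoregulation model parameters, indexed by the
# autoregulation index ARI 0 (absent) .. 9 (best): time constant T (s),
# damping D, autoregulatory gain K. Transcribed from Tiecks FP, Lassen NA
# et al., "Comparison of static and dynamic cerebral autoregulation
# measurements", Stroke 1995;26(6):1014-9.
TIECKS_PARAMS: dict[int, tuple[float, float, float]] = {
    0: (2.00, 1.70, 0.00),
    1: (2.00, 1.60, 0.20),
    2: (2.00, 1.50, 0.40),
    3: (2.00, 1.15, 0.60),
    4: (2.00, 0.90, 0.80),
    5: (1.90, 0.75, 0.90),
    6: (1.60, 0.65, 0.94),
    7: (1.20, 0.55, 0.96),
    8: (0.87, 0.52, 0.97),
    9: (0.65, 0.50, 0.98),
}

#: critical closing pressure assumed by the Tiecks model (mmHg)
TIECKS_CRCP_MMHG = 12.0


def generate_fv_tiecks(
    abp: Signal,
    ari: int,
    baseline_cm_s: float = 60.0,
    seed: int | np.random.SeedSequence = 0,
    noise_sd_cm_s: float = 0.5,
) -> Signal:
    """Flow velocity from the Tiecks-Lassen second-order state model.

    The normalized pressure deviation dP drives the discrete recursion

        x1[n] = x1[n-1] + (dP[n] - x2[n-1]) / (f*T)
        x2[n] = x2[n-1] + (x1[n] - 2*D*x2[n-1]) / (f*T)
        FV[n] = baseline * (1 + dP[n] - K*x2[n]) + noise

    with per-ARI parameters (T, D, K). ARI 0 has K=0 and reduces to a
    pressure-passive FV.
    """
    if ari not in TIECKS_PARAMS:
        raise ValidationError("ari must be an integer in 0..9")
    T, D, K = TIECKS_PARAMS[ari]
    rng = np.random.default_rng(seed)
    p = abp.values
    p_base = float(np.mean(p))
    dp = (p - p_base) / (p_base - TIECKS_CRCP_MMHG)
    f = abp.rate
    x1 = 0.0
    x2 = 0.0
    mv = np.empty(len(p))
    ft = f * T
    for i in range(len(p)):
        x1 = x1 + (dp[i] - x2) / ft
        x2 = x2 + (x1 - 2.0 * D * x2) / ft
        mv[i] = 1.0 + dp[i] - K * x2
    noise = noise_sd_cm_s * rng.standard_normal(len(p)) if noise_sd_cm_s > 0 else 0.0
    values = baseline_cm_s * mv + noise
    return Signal(times=abp.times.copy(), values=values, rate=abp.rate, label="FV")


# ---------------------------------------------------------------------------
# pupillometry generator
# ---------------------------------------------------------------------------

# population calibration: median and SD (IQR/1.349) of ICU pupillometry
NPI_SD = 0.53
PUPIL_DISTS = {  # variable -> (median, sd, lower bound, upper bound)
    "size_mm": (3.67, 1.45, 0.5, 9.0),
    "constriction_pct": (32.5, 10.3, 0.0, 100.0),
    "cv_mm_s": (3.61, 0.80, 0.0, np.inf),
    "latency_s": (0.24, 0.037, 0.0, np.inf),
}
EYE_NOISE_SD = 0.1  # between-eye NPI noise


def _truncnorm(
    rng: np.random.Generator, loc: float, sd: float, lo: float, hi: float, size
) -> np.ndarray:
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return sps.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def generate_pupillometry(
    mxa_values: np.ndarray,
    r2_target: float = 0.04,
    slope_sign: int = -1,
    npi_center: float = 4.33,
    seed: int | np.random.SeedSequence = 0,
    npi_sd: float = NPI_SD,
    eye_noise_sd: float = EYE_NOISE_SD,
) -> tuple[list[tuple[EyeReading, EyeReading]], np.ndarray]:
    """Per-patient eye pairs with a tunable NPI-Mxa association.

    The patient-level NPI is npi_center + b*(Mxa - mean(Mxa)) + eps with b
    solved from r2_target = b^2*Var(Mxa) / (b^2*Var(Mxa) + sigma_eps^2)
    holding the total NPI variance at npi_sd^2, and sign(b) = slope_sign
    (negative by default: impaired autoregulation trends to lower NPI).
    Each eye is the patient value plus small independent noise, truncated
    to the device's 0-5 NPI scale. The remaining variables (size,
    constriction, velocity, latency) are drawn independently of Mxa.

    Returns (eye pairs, patient-level NPI residuals eps).
    """
    if not 0.0 <= r2_target < 1.0:
        raise ValidationError("r2_target must be in [0, 1)")
    if slope_sign not in (-1, 1):
        raise ValidationError("slope_sign must be -1 or +1")
    mxa_values = np.asarray(mxa_values, dtype=float)
    n = len(mxa_values)
    rng = np.random.default_rng(seed)

    var_mxa = float(np.var(mxa_values))
    if r2_target > 0 and var_mxa == 0:
        raise ValidationError("Var(Mxa) = 0: cannot target a nonzero r^2")
    total_var = npi_sd**2
    sigma_eps = np.sqrt((1.0 - r2_target) * total_var)
    b = 0.0
    if r2_target > 0:
        b = slope_sign * np.sqrt(r2_target * total_var / var_mxa)

    eps = sigma_eps * rng.standard_normal(n)
    npi_patient = npi_center + b * (mxa_values - mxa_values.mean()) + eps

    others = {
        name: _truncnorm(rng, med, sd, lo, hi, size=(n, 2))
        for name, (med, sd, lo, hi) in PUPIL_DISTS.items()
    }
    eye_noise = eye_noise_sd * rng.standard_normal((n, 2))

    pairs: list[tuple[EyeReading, EyeReading]] = []
    for i in range(n):
        eyes = []
        for j in (0, 1):
            npi = float(np.clip(npi_patient[i] + eye_noise[i, j], 0.0, 5.0))
            eyes.append(
                EyeReading(
                    npi=npi,
                    size_mm=float(others["size_mm"][i, j]),
                    constriction_pct=float(others["constriction_pct"][i, j]),
                    cv_mm_s=float(others["cv_mm_s"][i, j]),
                    latency_s=float(others["latency_s"][i, j]),
                )
            )
        pairs.append((eyes[0], eyes[1]))
    return pairs, eps


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

#: pilot-calibration cache: (duration, rate, mean_abp, fv_baseline) -> curve
_W_CURVE_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}

PILOT_W_GRID = np.linspace(0.0, 1.0, 21)
PILOT_SEEDS_PER_W = 24
PILOT_BASE_SEED = 20200731  # fixed: the calibration curve is part of the model


def calibrate_w_curve(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Pilot-simulate the monotone map w -> E[Mxa] on a grid.

    The curve is estimated once per (duration, rate, pressure, baseline)
    setting from a fixed pilot seed and cached; it is a property of the
    generator, not of the cohort seed, so cohorts remain pure functions of
    their own seed.
    """
    key = (config.duration_s, config.rate_hz, config.mean_abp_mmhg, config.fv_baseline_cm_s)
    if key in _W_CURVE_CACHE:
        return _W_CURVE_CACHE[key]
    mxa_cfg = MxaConfig(min_duration_s=min(360.0, config.duration_s))
    means = []
    for wi, w in enumerate(PILOT_W_GRID):
        vals = []
        for s in range(PILOT_SEEDS_PER_W):
            ss = np.random.SeedSequence([PILOT_BASE_SEED, wi, s])
            s_abp, s_fv = ss.spawn(2)
            abp = generate_abp(
                config.duration_s, config.rate_hz, config.mean_abp_mmhg, seed=s_abp
            )
            fv = generate_fv(abp, w, config.fv_baseline_cm_s, seed=s_fv)
            vals.append(compute_mxa(abp, fv, mxa_cfg).mxa)
        means.append(float(np.mean(vals)))
    curve = np.asarray(means)
    # enforce monotonicity for a well-defined inverse
    curve = np.maximum.accumulate(curve)
    _W_CURVE_CACHE[key] = (PILOT_W_GRID.copy(), curve)
    return _W_CURVE_CACHE[key]


def invert_w_curve(intended_mxa: np.ndarray, grid: np.ndarray, curve: np.ndarray) -> np.ndarray:
    """Map intended Mxa values to passivity weights via the pilot curve;
    targets outside the achievable range clamp to w=0 or w=1."""
    return np.interp(intended_mxa, curve, grid, left=grid[0], right=grid[-1])


def generate_cohort(
    config: SimConfig, out_dir: Path | str | None = None
) -> tuple[list[PatientRecord], GroundTruth]:
    """Generate a full cohort: signals, computed Mxa, pupillometry, labels.

    Per-patient passivity is sampled so that the computed-Mxa distribution
    approximates the target median/IQR: intended Mxa is drawn from a
    normal(median, sd) truncated to [-1, 1] and mapped through the inverse
    of the pilot-calibrated w -> E[Mxa] curve. Pupillometry is generated
    per group from the *computed* Mxa values, so r2_target refers to the
    association the analysis pipeline actually measures.

    When out_dir is given, writes per-patient signal CSVs, the cohort CSV
    and ground_truth.json there (deterministic contents for a fixed seed).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_septic + config.n_nonseptic
    if n == 0:
        raise ValidationError("empty cohort requested")
    groups = ["septic"] * config.n_septic + ["non_septic"] * config.n_nonseptic
    ids = [f"P{i + 1:03d}" for i in range(n)]

    if config.passivity_w is not None:
        w = np.full(n, float(config.passivity_w))
        intended = np.full(n, np.nan)
    else:
        grid, curve = calibrate_w_curve(config)
        a = (-1.0 - config.mxa_pop_median) / config.mxa_pop_sd
        b = (1.0 - config.mxa_pop_median) / config.mxa_pop_sd
        intended = sps.truncnorm.rvs(
            a, b, loc=config.mxa_pop_median, scale=config.mxa_pop_sd,
            size=n, random_state=rng,
        )
        w = invert_w_curve(intended, grid, curve)

    mxa_cfg = MxaConfig(min_duration_s=min(360.0, config.duration_s))
    ss = np.random.SeedSequence([int(rng.integers(2**31)), 1])
    seeds = ss.spawn(2 * n)
    records: list[PatientRecord] = []
    computed = np.empty(n)
    signals = []
    for i in range(n):
        abp = generate_abp(
            config.duration_s, config.rate_hz, config.mean_abp_mmhg, seed=seeds[2 * i]
        )
        fv = generate_fv(abp, w[i], config.fv_baseline_cm_s, seed=seeds[2 * i + 1])
        computed[i] = compute_mxa(abp, fv, mxa_cfg).mxa
        signals.append((abp, fv))

    # pupillometry per group, associated with the computed Mxa
    pairs: list = [None] * n
    residuals = np.empty(n)
    for gi, group in enumerate(("septic", "non_septic")):
        idx = [i for i in range(n) if groups[i] == group]
        if not idx:
            continue
        # a degenerate group (fewer than 2 patients or zero Mxa variance)
        # cannot carry an association: fall back to the null
        g_r2 = config.r2_target if np.var(computed[idx]) > 0 else 0.0
        g_pairs, g_eps = generate_pupillometry(
            computed[idx],
            r2_target=g_r2,
            slope_sign=config.slope_sign,
            npi_center=config.npi_center,
            seed=np.random.SeedSequence([int(rng.integers(2**31)), 2, gi]),
        )
        for k, i in enumerate(idx):
            pairs[i] = g_pairs[k]
            residuals[i] = g_eps[k]

    threshold = mxa_cfg.impaired_threshold
    for i in range(n):
        records.append(
            PatientRecord(
                patient_id=ids[i],
                group=groups[i],
                left_eye=pairs[i][0],
                right_eye=pairs[i][1],
                abp=signals[i][0],
                fv=signals[i][1],
                abp_file=f"{ids[i]}_abp.csv",
                fv_file=f"{ids[i]}_fv.csv",
            )
        )
    truth = GroundTruth(
        patient_ids=ids,
        passivity_w=w,
        intended_mxa=intended,
        computed_mxa=computed,
        npi_residual=residuals,
        intended_car=["impaired" if m > threshold else "intact" for m in computed],
    )
    if out_dir is not None:
        write_cohort_dir(records, truth, out_dir)
    return records, truth


def write_cohort_dir(
    records: list[PatientRecord], truth: GroundTruth, out_dir: Path | str
) -> None:
    """Write per-patient signal CSVs, cohort.csv and ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in records:
        write_signal(rec.abp, out / rec.abp_file)
        write_signal(rec.fv, out / rec.fv_file)
    write_cohort(records, out / "cohort.csv")
    payload = {
        "patient_ids": truth.patient_ids,
        "passivity_w": truth.passivity_w.tolist(),
        "intended_mxa": truth.intended_mxa.tolist(),
        "computed_mxa": truth.computed_mxa.tolist(),
        "npi_residual": truth.npi_residual.tolist(),
        "intended_car": truth.intended_car,
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(payload, fh, indent=1)


def config_defaults() -> dict:
    """Flat key/value view of SimConfig defaults (for `simulate --show-defaults`)."""
    return dataclasses.asdict(SimConfig())
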