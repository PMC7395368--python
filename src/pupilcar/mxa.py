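"""Mxa mean-flow-index computation.

The Mxa index quantifies cerebral autoregulation from several minutes of
paired arterial blood pressure (ABP, mmHg) and middle-cerebral-artery flow
velocity (FV, cm/s): both signals are averaged on a 10-s moving window
with 50% overlap and the Pearson correlation between the two window-mean
series is the index. Because flow-velocity changes mirror cerebral blood
flow changes, Mxa > 0.3 indicates pressure-passive (impaired)
autoregulation; Mxa <= 0.3 is read as intact.

Artifact handling (range gates, spike and dropout detection) precedes the
averaging; the specific rules are configurable since clinical practice
varies. Raw pressure (not beat-averaged MAP) enters the averaging — the
10-s means suppress pulsatility either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signal_io import Signal, ValidationError


class UnusableRecordingError(Exception):
    """Too little clean overlapping signal to compute an index."""


class UndefinedCorrelationError(ValueError):
    """Pearson correlation undefined (constant input series)."""


@dataclass(frozen=True)
class ArtifactRules:
    """Sample-level artifact gates.

    abp_range / fv_range are physiologic plausibility gates (mmHg, cm/s).
    jump_sd flags one-sample jumps larger than that multiple of the robust
    SD (1.4826*MAD) of the first differences. flat_run_s flags runs of
    identical values longer than this many seconds (sensor dropout).
    """

    abp_range: tuple[float, float] = (20.0, 250.0)
    fv_range: tuple[float, float] = (0.0, 300.0)
    jump_sd: float = 5.0
    flat_run_s: float = 2.0


@dataclass(frozen=True)
class MxaConfig:
    window_s: float = 10.0
    overlap_frac: float = 0.5
    #: minimum usable common span; the study recorded 8 +/- 2 min
    min_duration_s: float = 360.0
    impaired_threshold: float = 0.3
    #: windows with more than this fraction of samples missing are dropped
    max_missing_frac: float = 0.25
    artifact_rules: ArtifactRules = field(default_factory=ArtifactRules)

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_frac < 1.0:
            raise ValidationError("overlap_frac must be in [0, 1)")
        if self.window_s <= 0:
            raise ValidationError("window_s must be positive")
        if not -1.0 < self.impaired_threshold < 1.0:
            raise ValidationError("impaired_threshold must be in (-1, 1)")


@dataclass(frozen=True)
class MxaResult:
    """Windowed means, the Mxa value and the autoregulation call."""

    window_times: np.ndarray
    bp_windows: np.ndarray
    fv_windows: np.ndarray
    n_windows: int
    mxa: float
    car_status: str  # "impaired" | "intact"
    qc: dict


def remove_artifacts(signal: Signal, rules: ArtifactRules | None = None) -> Signal:
    """Flag artifactual samples as missing (NaN); values are never edited.

    Three rules: out-of-physiologic-range samples, one-sample jumps larger
    than ``jump_sd`` robust SDs of the first differences, and flat runs
    (identical consecutive values) longer than ``flat_run_s`` seconds.
    An all-flagged signal is returned as-is and fails downstream.
    """
    if rules is None:
        rules = ArtifactRules()
    v = signal.values.copy()
    flagged = np.zeros(len(v), dtype=bool)
    finite = np.isfinite(v)

    lo, hi = rules.abp_range if signal.label == "ABP" else rules.fv_range
    flagged |= finite & ((v < lo) | (v > hi))

    # spike gate: robust SD of first differences over unflagged samples
    dv = np.diff(v)
    good_dv = np.isfinite(dv)
    if good_dv.sum() >= 10:
        mad = np.median(np.abs(dv[good_dv] - np.median(dv[good_dv])))
        robust_sd = 1.4826 * mad
        if robust_sd > 0:
            spikes = good_dv & (np.abs(dv) > rules.jump_sd * robust_sd)
            # flag the sample the jump lands on
            flagged[1:] |= spikes

    # dropout gate: runs of identical values longer than flat_run_s
    run_len = int(round(rules.flat_run_s * signal.rate))
    if run_len >= 2 and len(v) > run_len:
        n = len(v)
        same = np.concatenate([[False], np.isfinite(v[1:]) & (v[1:] == v[:-1])])
        idx = np.arange(n)
        last_break = np.maximum.accumulate(np.where(~same, idx, 0))
        run = idx - last_break  # samples since the run started
        hits = np.nonzero(run >= run_len)[0]
        if len(hits):
            # group contiguous hits and flag each full run
            splits = np.nonzero(np.diff(hits) > 1)[0] + 1
            for grp in np.split(hits, splits):
                flagged[grp[0] - run[grp[0]]: grp[-1] + 1] = True

    v[flagged] = np.nan
    return replace(signal, values=v)


def block_average(
    signal: Signal,
    window_s: float = 10.0,
    overlap_frac: float = 0.5,
    max_missing_frac: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window means on a moving window.

    Windows start at the signal's first sample and advance by
    window_s*(1-overlap_frac) (5 s at defaults); a final partial window is
    dropped, as is any window with more than ``max_missing_frac`` of its
    samples missing (its mean is NaN). Returns (window_start_times, means).
    """
    if signal.duration_s < window_s:
        raise ValidationError("signal shorter than one window")
    n_per_win = int(round(window_s * signal.rate))
    n_step = window_s * (1.0 - overlap_frac) * signal.rate
    n = len(signal)
    starts = []
    means = []
    k = 0
    while True:
        i0 = int(round(k * n_step))
        i1 = i0 + n_per_win
        if i1 > n:
            break
        chunk = signal.values[i0:i1]
        miss = np.isnan(chunk)
        if miss.mean() > max_missing_frac:
            means.append(np.nan)
        else:
            means.append(float(np.nanmean(chunk)))
        starts.append(signal.times[i0])
        k += 1
    if not starts:
        raise ValidationError("no complete window fits the signal")
    return np.asarray(starts), np.asarray(means)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; errors on constant input rather than
    returning a numeric 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D of equal length")
    if len(x) < 2:
        raise ValidationError("need at least 2 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant series")
    xm = x - x.mean()
    ym = y - y.mean()
    r = float(np.dot(xm, ym) / np.sqrt(np.dot(xm, xm) * np.dot(ym, ym)))
    return float(np.clip(r, -1.0, 1.0))


def _resample(signal: Signal, rate: float, t0: float, t1: float) -> Signal:
    """Linear-interpolation resample onto a uniform grid [t0, t1) at rate."""
    n = int(np.floor((t1 - t0) * rate + 1e-9))
    times = t0 + np.arange(n) / rate
    good = np.isfinite(signal.values)
    if good.sum() < 2:
        values = np.full(n, np.nan)
    else:
        values = np.interp(times, signal.times[good], signal.values[good])
        # a resampled point falling in a missing stretch stays missing
        nearest = np.searchsorted(signal.times, times)
        nearest = np.clip(nearest, 0, len(signal) - 1)
        values[~good[nearest]] = np.nan
    return Signal(times=times, values=values, rate=rate, label=signal.label)


def compute_mxa(abp: Signal, fv: Signal, config: MxaConfig | None = None) -> MxaResult:
    """Full Mxa chain: crop to common span, remove artifacts, 10-s/50%
    block-average both signals, drop window pairs with a missing side,
    correlate, classify.

    car_status is "impaired" iff mxa > config.impaired_threshold (strict:
    the threshold itself classifies intact).
    """
    if config is None:
        config = MxaConfig()
    if abp.label != "ABP" or fv.label != "FV":
        raise ValidationError("expected an ABP and an FV signal")

    t0 = max(abp.times[0], fv.times[0])
    t1 = min(abp.times[-1] + 1.0 / abp.rate, fv.times[-1] + 1.0 / fv.rate)
    if t1 - t0 < config.min_duration_s:
        raise UnusableRecordingError(
            f"common span {t1 - t0:.1f} s < required {config.min_duration_s:.1f} s"
        )

    abp = remove_artifacts(abp, config.artifact_rules)
    fv = remove_artifacts(fv, config.artifact_rules)
    qc = {
        "abp_flagged_frac": float(np.isnan(abp.values).mean()),
        "fv_flagged_frac": float(np.isnan(fv.values).mean()),
    }

    # align on a common uniform grid at the lower of the two rates
    rate = min(abp.rate, fv.rate)
    abp_c = _resample(abp, rate, t0, t1)
    fv_c = _resample(fv, rate, t0, t1)

    ta, bp_means = block_average(
        abp_c, config.window_s, config.overlap_frac, config.max_missing_frac
    )
    tf, fv_means = block_average(
        fv_c, config.window_s, config.overlap_frac, config.max_missing_frac
    )
    assert len(ta) == len(tf)

    keep = np.isfinite(bp_means) & np.isfinite(fv_means)
    qc["windows_total"] = int(len(keep))
    qc["windows_dropped"] = int((~keep).sum())
    qc["windows_dropped_frac"] = float((~keep).mean())
    if keep.sum() < 2:
        raise UnusableRecordingError(f"fewer than 2 usable window pairs (qc: {qc})")

    try:
        mxa = pearson_r(bp_means[keep], fv_means[keep])
    except UndefinedCorrelationError as exc:
        raise UnusableRecordingError(f"constant window means (qc: {qc})") from exc
    status = "impaired" if mxa > config.impaired_threshold else "intact"
    return MxaResult(
        window_times=ta[keep],
        bp_windows=bp_means[keep],
        fv_windows=fv_means[keep],
        n_windows=int(keep.sum()),
        mxa=mxa,
        car_status=status,
        qc=qc,
    )
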