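import hashlib
from pathlib import Path

import numpy as np
import pytest

from pupilcar import (
    MxaConfig,
    SimConfig,
    ValidationError,
    aggregate_eyes,
    compute_mxa,
    generate_abp,
    generate_cohort,
    generate_fv,
    generate_fv_tiecks,
    generate_pupillometry,
    pearson_test,
)
from pupilcar.synthetic import SLOW_CUTOFF_HZ, slow_component


# ---------------------------------------------------------------------------
# ABP generator
# ---------------------------------------------------------------------------

def test_abp_deterministic_for_fixed_seed():
    a = generate_abp(duration_s=60.0, seed=9)
    b = generate_abp(duration_s=60.0, seed=9)
    assert np.array_equal(a.values, b.values)
    assert not np.array_equal(a.values, generate_abp(duration_s=60.0, seed=10).values)


def test_zero_amplitudes_give_constant_mean():
    sig = generate_abp(
        duration_s=30.0, mean_mmhg=85.0, seed=0,
        slow_rms_mmhg=0.0, cardiac_amp_mmhg=0.0, noise_sd_mmhg=0.0,
    )
    assert np.allclose(sig.values, 85.0)


def test_slow_band_rms_matches_configuration():
    """Band-pass-extracted slow-wave RMS within 10% of the configured value."""
    rms = []
    for seed in range(50):
        sig = generate_abp(duration_s=480.0, seed=seed, slow_rms_mmhg=5.0,
                           cardiac_amp_mmhg=2.0, noise_sd_mmhg=0.5)
        slow = slow_component(sig)  # < 0.15 Hz band
        rms.append(np.sqrt(np.mean(slow**2)))
    assert np.mean(rms) == pytest.approx(5.0, rel=0.10)


def test_abp_rejects_nonpositive_duration():
    with pytest.raises(ValidationError):
        generate_abp(duration_s=0.0)


# ---------------------------------------------------------------------------
# mixture FV generator
# ---------------------------------------------------------------------------

def test_fv_rejects_w_outside_unit_interval():
    abp = generate_abp(duration_s=60.0, seed=0)
    with pytest.raises(ValidationError):
        generate_fv(abp, passivity_w=1.2)


def test_fully_buffered_fv_mxa_centered_at_zero():
    """At w=0 the FV shares no slow-wave signal with the ABP: Mxa scatters
    around zero. An 8-min recording has only a few dozen independent slow
    fluctuations, so the scatter is wide (SD ~ 0.2): the bound here is the
    simulation-measured one."""
    vals = []
    for seed in range(60):
        abp = generate_abp(seed=seed)
        fv = generate_fv(abp, 0.0, seed=5000 + seed)
        vals.append(compute_mxa(abp, fv).mxa)
    vals = np.array(vals)
    assert abs(vals.mean()) < 0.1
    assert np.mean(np.abs(vals) < 0.2) >= 0.5


def test_mxa_monotone_in_passivity_weight():
    """Mean Mxa is non-decreasing along the w grid 0, 0.25, ..., 1."""
    means = []
    for w in (0.0, 0.25, 0.5, 0.75, 1.0):
        m = []
        for seed in range(25):
            abp = generate_abp(seed=seed)
            m.append(compute_mxa(abp, generate_fv(abp, w, seed=7000 + seed)).mxa)
        means.append(np.mean(m))
    assert all(b >= a for a, b in zip(means, means[1:]))
    assert means[0] < 0.2 and means[-1] > 0.95


def test_fv_slow_component_spectrum_matched(rng):
    """The independent process E has the same band as the shared component:
    the FV at w=0 carries no power above the slow cut-off beyond noise."""
    abp = generate_abp(seed=31)
    fv = generate_fv(abp, 0.0, seed=32, noise_sd_cm_s=0.0)
    spec = np.abs(np.fft.rfft(fv.values - fv.values.mean())) ** 2
    f = np.fft.rfftfreq(len(fv), d=1.0 / fv.rate)
    in_band = spec[(f > 0) & (f <= SLOW_CUTOFF_HZ)].sum()
    out_band = spec[f > SLOW_CUTOFF_HZ].sum()
    assert out_band / in_band < 1e-20


# ---------------------------------------------------------------------------
# Tiecks-Lassen FV generator
# ---------------------------------------------------------------------------

def test_tiecks_absent_autoregulation_is_pressure_passive():
    m = []
    for seed in range(20):
        abp = generate_abp(seed=seed)
        m.append(compute_mxa(abp, generate_fv_tiecks(abp, 0, seed=300 + seed)).mxa)
    assert np.median(m) > 0.9


def test_tiecks_best_autoregulation_buffers_pressure():
    m0, m9 = [], []
    for seed in range(20):
        abp = generate_abp(seed=seed)
        m0.append(compute_mxa(abp, generate_fv_tiecks(abp, 0, seed=300 + seed)).mxa)
        m9.append(compute_mxa(abp, generate_fv_tiecks(abp, 9, seed=300 + seed)).mxa)
    assert np.median(m9) < np.median(m0)


def test_tiecks_deterministic_and_validated():
    abp = generate_abp(duration_s=60.0, seed=1)
    a = generate_fv_tiecks(abp, 5, seed=2)
    b = generate_fv_tiecks(abp, 5, seed=2)
    assert np.array_equal(a.values, b.values)
    with pytest.raises(ValidationError):
        generate_fv_tiecks(abp, 10)


# ---------------------------------------------------------------------------
# pupillometry generator
# ---------------------------------------------------------------------------

def _patient_npi(pairs):
    return np.array([aggregate_eyes(l, r).mean_npi for l, r in pairs])


def test_null_association_r2_near_zero(rng):
    r2s = []
    for seed in range(100):
        mxa = rng.uniform(-0.5, 1.0, size=500)
        pairs, _ = generate_pupillometry(mxa, r2_target=0.0, seed=seed)
        r2s.append(pearson_test(mxa, _patient_npi(pairs)).r_squared)
    assert np.mean(r2s) < 0.01


def test_noise_free_limit_npi_affine_in_mxa(rng):
    mxa = rng.uniform(-0.5, 1.0, size=50)
    pairs, _ = generate_pupillometry(
        mxa, r2_target=1.0 - 1e-12, seed=0, npi_sd=0.05, eye_noise_sd=0.0,
    )
    res = pearson_test(mxa, _patient_npi(pairs))
    assert abs(res.r) > 0.999999
    assert res.r < 0  # default slope: impaired (high Mxa) -> lower NPI


def test_degenerate_mxa_variance_rejected():
    with pytest.raises(ValidationError):
        generate_pupillometry(np.full(10, 0.4), r2_target=0.05)


def test_eye_readings_respect_device_ranges(rng):
    mxa = rng.uniform(-1.0, 1.0, size=200)
    pairs, _ = generate_pupillometry(mxa, r2_target=0.1, seed=3)
    for left, right in pairs:
        for eye in (left, right):
            assert eye.validate() == []
            assert 0.0 <= eye.npi <= 5.0


def test_non_npi_variables_uncorrelated_with_mxa(rng):
    mxa = rng.uniform(-0.5, 1.0, size=2000)
    pairs, _ = generate_pupillometry(mxa, r2_target=0.1, seed=4)
    for attr in ("size_mm", "constriction_pct", "cv_mm_s", "latency_s"):
        vals = np.array(
            [(getattr(l, attr) + getattr(r, attr)) / 2 for l, r in pairs]
        )
        assert abs(pearson_test(mxa, vals).r) < 0.1


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

def test_cohort_ground_truth_aligned(small_cohort):
    records, truth = small_cohort
    assert len(truth) == len(records) == 18
    assert len(truth.passivity_w) == len(truth.computed_mxa) == 18
    assert all(0.0 <= w <= 1.0 for w in truth.passivity_w)
    assert sum(r.group == "septic" for r in records) == 10


def test_cohort_directory_deterministic(tmp_path):
    cfg = SimConfig(n_septic=2, n_nonseptic=1, duration_s=120.0, seed=77)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    generate_cohort(cfg, out_dir=d1)
    generate_cohort(cfg, out_dir=d2)
    files1 = sorted(p.name for p in d1.iterdir())
    assert files1 == sorted(p.name for p in d2.iterdir())
    assert "cohort.csv" in files1 and "ground_truth.json" in files1
    for name in files1:
        h1 = hashlib.sha256((d1 / name).read_bytes()).hexdigest()
        h2 = hashlib.sha256((d2 / name).read_bytes()).hexdigest()
        assert h1 == h2, name


def test_cohort_car_labels_follow_threshold(small_cohort):
    records, truth = small_cohort
    for m, lab in zip(truth.computed_mxa, truth.intended_car):
        assert lab == ("impaired" if m > 0.3 else "intact")


def test_fixed_passivity_overrides_sampling():
    cfg = SimConfig(n_septic=2, n_nonseptic=2, duration_s=120.0, seed=5, passivity_w=1.0)
    records, truth = generate_cohort(cfg)
    assert np.all(truth.passivity_w == 1.0)
    assert all(lab == "impaired" for lab in truth.intended_car)


def test_infeasible_population_target_rejected():
    with pytest.raises(ValidationError):
        SimConfig(mxa_pop_median=1.5)
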