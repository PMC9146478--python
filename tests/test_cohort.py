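"""Synthetic cohort generator: geometry, determinism, severity structure."""

import dataclasses

import numpy as np
import pytest

from vagdx.cohort import (DEMOGRAPHICS, generate_cohort, generate_encoder_trace,
                          generate_profiles, generate_recording)
from vagdx.types import Chain, GeneratorConfig, Group, Sex, SubjectProfile


def test_encoder_trace_single_cycle_hits_both_hard_stops():
    cfg = GeneratorConfig(n_cycles=1, jitter=0.0, encoder_noise_deg=0.0)
    trace = generate_encoder_trace(cfg, jitter_seed=0)
    assert trace.angle.min() == pytest.approx(0.0, abs=1.0)
    assert trace.angle.max() == pytest.approx(90.0, abs=0.5)
    assert np.all(trace.angle >= 0.0) and np.all(trace.angle <= 90.0)


def test_encoder_trace_sample_count_matches_protocol():
    cfg = GeneratorConfig(n_cycles=10, cycle_period=2.0, jitter=0.0, idle_s=1.0)
    trace = generate_encoder_trace(cfg, jitter_seed=1)
    # 10 cycles x 2 s x 10 Hz motion samples plus 2 s idle padding
    assert trace.angle.size == pytest.approx(200 + 20, abs=2)


def test_cycle_duration_jitter_bounds():
    cfg = GeneratorConfig(n_cycles=10, cycle_period=2.0, jitter=0.1)
    for seed in range(5):
        trace = generate_encoder_trace(cfg, jitter_seed=seed)
        assert np.all(trace.cycle_durations >= 1.8 - 1e-12)
        assert np.all(trace.cycle_durations <= 2.2 + 1e-12)


def test_recording_determinism_and_quantization(oa_subject, small_config):
    a = generate_recording(oa_subject, Chain.OKC, small_config, seed=5)
    b = generate_recording(oa_subject, Chain.OKC, small_config, seed=5)
    np.testing.assert_array_equal(a.acoustic, b.acoustic)
    np.testing.assert_array_equal(a.encoder, b.encoder)
    assert a.truth == b.truth
    assert a.acoustic.dtype.kind == "i"
    assert a.acoustic.min() >= 0
    assert a.acoustic.max() <= 2**small_config.quant_bits - 1


def test_zero_burst_rate_gives_empty_burst_log(hc_subject, small_config):
    cfg = dataclasses.replace(small_config,
                              burst_rate_per_grade=(0.0, 1.0, 2.0, 3.0, 4.0))
    rec = generate_recording(hc_subject, Chain.CKC, cfg, seed=2)
    assert rec.truth["burst_times"] == []


def test_invalid_grade_rejected(small_config):
    with pytest.raises(ValueError):
        SubjectProfile(subject_id="X", group=Group.OA, icrs_grade=0, age=50,
                       sex=Sex.F, height=1.7, weight=80, bmi=80 / 1.7**2)


def test_burst_count_matches_poisson_mean(oa_subject):
    """Empirical mean burst count over 200 grade-3 recordings ~ Poisson mean."""
    cfg = GeneratorConfig(n_cycles=3, idle_s=0.5)
    rate = cfg.burst_rate_per_grade[3]
    counts = [len(generate_recording(oa_subject, Chain.OKC, cfg, seed=s)
                  .truth["burst_times"]) for s in range(200)]
    expected = cfg.n_cycles * rate
    se = np.sqrt(expected / 200)
    assert abs(np.mean(counts) - expected) < 3 * se


def test_burst_energy_monotone_in_grade():
    """Mean acoustic energy is non-decreasing in ICRS grade when only the
    burst process is active (all other sources silenced)."""
    cfg = GeneratorConfig(n_cycles=2, idle_s=0.5, drift_amp=0.0, hum_amp=0.0,
                          friction_amp=0.0, noise_std=1e-6)
    energies = []
    for grade in range(5):
        group = Group.HC if grade == 0 else Group.OA
        subj = SubjectProfile(subject_id=f"G{grade}", group=group,
                              icrs_grade=grade, age=50, sex=Sex.M,
                              height=1.75, weight=80, bmi=80 / 1.75**2)
        e = []
        for s in range(100):
            rec = generate_recording(subj, Chain.OKC, cfg, seed=s)
            x = rec.acoustic_float()
            e.append(float(np.mean(x**2)))
        energies.append(np.mean(e))
    assert all(b >= a for a, b in zip(energies, energies[1:]))


def test_cohort_counts_and_demographics():
    cfg = GeneratorConfig(n_hc=33, n_oa=34, seed=12)
    profiles = generate_profiles(cfg)
    hc = [p for p in profiles if p.group == Group.HC]
    oa = [p for p in profiles if p.group == Group.OA]
    assert (len(hc), len(oa)) == (33, 34)
    for group, sample in ((Group.HC, hc), (Group.OA, oa)):
        mean, sd = DEMOGRAPHICS[group][0], DEMOGRAPHICS[group][1]
        ages = np.array([p.age for p in sample])
        assert abs(ages.mean() - mean) < 3 * sd / np.sqrt(len(sample))
    for p in profiles:
        assert abs(p.bmi - p.weight / p.height**2) < 1e-6
        assert (p.icrs_grade == 0) == (p.group == Group.HC)


def test_cohort_recording_counts_and_determinism():
    cfg = GeneratorConfig(n_hc=3, n_oa=2, n_cycles=2, seed=9)
    cohort = generate_cohort(cfg, chains=(Chain.OKC,))
    # HC contribute both knees, OA the operated knee only
    assert len(cohort.recordings) == 3 * 2 + 2
    again = generate_cohort(cfg, chains=(Chain.OKC,))
    for a, b in zip(cohort.recordings, again.recordings):
        np.testing.assert_array_equal(a.acoustic, b.acoustic)
    assert set(cohort.manifest()["group"]) == {"HC", "OA"}


def test_empty_group_rejected():
    with pytest.raises(ValueError):
        generate_cohort(GeneratorConfig(n_hc=0, n_oa=5))
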