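"""Synthetic VAG cohort generator.

Emulates the acquisition geometry and statistical structure the pipeline
assumes so every downstream stage is testable without clinical data: ~2 s
90-0-90 knee cycles with per-cycle duration jitter, grade-dependent
Poisson-placed damped-sinusoid bursts ("clicks" from cartilage lesions), an
angular-velocity-tracking friction term, slow sensor drift (integrated
low-pass noise), broadband background noise, 50 Hz hum, and 10-bit
quantization.  No cartilage tribology is modeled — only the signal
morphology the preprocessing and feature stages are built to handle.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .types import Chain, GeneratorConfig, Group, RawRecording, Sex, SubjectProfile

# Per-group demographic targets: (age mean, age sd, height mean, height sd,
# weight mean, weight sd, P(male)).
DEMOGRAPHICS = {
    Group.HC: (24.10, 5.56, 1.71, 0.09, 65.16, 15.10, 9 / 33),
    Group.OA: (56.15, 12.99, 1.69, 0.09, 89.08, 14.30, 15 / 34),
}

_CHAIN_CODE = {Chain.OKC: 1, Chain.CKC: 2}


def _sub_rng(*keys: int) -> np.random.Generator:
    """Deterministic child generator from a tuple of integer keys."""
    return np.random.default_rng([int(k) & 0x7FFFFFFF for k in keys])


def _id_key(s: str) -> int:
    return zlib.crc32(s.encode("utf-8"))


@dataclass
class EncoderTrace:
    """Angle trace plus the ground-truth cycle boundary times (s)."""

    angle: np.ndarray           # degrees at fs_encoder
    cycle_bounds: list[tuple[float, float]]
    total_duration: float
    cycle_durations: np.ndarray = field(default_factory=lambda: np.empty(0))


def _cycle_durations(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    j = config.jitter
    return config.cycle_period * (1.0 + rng.uniform(-j, j, size=config.n_cycles))


def _angle_at(t: np.ndarray, starts: np.ndarray, durations: np.ndarray,
              idle_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-cosine angle (deg) and angular velocity (deg/s) at times t.

    Each cycle runs 90 -> 0 -> 90 as 45 + 45*cos(2*pi*tau/T); outside motion
    the knee rests at 90 degrees against the hard stop.
    """
    angle = np.full_like(t, 90.0, dtype=float)
    omega = np.zeros_like(t, dtype=float)
    for t0, T in zip(starts, durations):
        m = (t >= t0) & (t < t0 + T)
        tau = t[m] - t0
        angle[m] = 45.0 + 45.0 * np.cos(2 * np.pi * tau / T)
        omega[m] = -45.0 * (2 * np.pi / T) * np.sin(2 * np.pi * tau / T)
    return angle, omega


def generate_encoder_trace(config: GeneratorConfig, jitter_seed: int) -> EncoderTrace:
    """Encoder trace of ``n_cycles`` 90-0-90 excursions with idle padding."""
    rng = _sub_rng(jitter_seed, 11)
    durations = _cycle_durations(config, rng)
    starts = config.idle_s + np.concatenate(([0.0], np.cumsum(durations[:-1])))
    total = config.idle_s * 2 + durations.sum()
    t = np.arange(int(round(total * config.fs_encoder))) / config.fs_encoder
    angle, _ = _angle_at(t, starts, durations, config.idle_s)
    if config.encoder_noise_deg > 0:
        angle = angle + rng.normal(0.0, config.encoder_noise_deg, angle.size)
    angle = np.clip(angle, 0.0, 90.0)
    bounds = [(s, s + T) for s, T in zip(starts, durations)]
    return EncoderTrace(angle=angle, cycle_bounds=bounds,
                        total_duration=total, cycle_durations=durations)


def _sos_lowpass(cutoff: float, fs: float, order: int = 4):
    return sps.butter(order, cutoff, btype="low", fs=fs, output="sos")


def _chain_gain(chain: Chain, omega: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Loading profile of the two protocols.

    OKC (seated extension): the extension phase (angle decreasing) carries the
    load, flexion is near-passive.  CKC (sit-to-stand): body weight loads both
    phases roughly equally.
    """
    if chain == Chain.OKC:
        return np.where(omega < 0, 1.0, 0.35)
    return np.full_like(omega, 0.75)


def generate_recording(subject: SubjectProfile, chain: Chain,
                       config: GeneratorConfig, seed: int,
                       knee: str = "") -> RawRecording:
    """Synthesize one two-channel recording. Deterministic in (seed, subject, chain, knee)."""
    if subject.group == Group.OA and subject.icrs_grade not in (1, 2, 3, 4):
        raise ValueError(f"invalid ICRS grade {subject.icrs_grade}")
    key = _id_key(subject.subject_id + knee)
    rng = _sub_rng(seed, key, _CHAIN_CODE[chain])

    trace = generate_encoder_trace(config, int(rng.integers(2**31)))
    fs = config.fs_acoustic
    n = int(round(trace.total_duration * fs))
    t = np.arange(n) / fs
    starts = np.array([b[0] for b in trace.cycle_bounds])
    durations = trace.cycle_durations
    angle, omega = _angle_at(t, starts, durations, config.idle_s)

    # broadband background (band-limited below Nyquist)
    x = config.noise_std * sps.sosfilt(_sos_lowpass(600.0, fs), rng.normal(size=n))

    # friction: narrowband noise whose envelope tracks |angular velocity|
    band = sps.butter(4, [50.0, 250.0], btype="band", fs=fs, output="sos")
    rough = sps.sosfilt(band, rng.normal(size=n))
    rough /= max(np.std(rough), 1e-12)
    env = np.abs(omega) / max(np.abs(omega).max(), 1e-12)
    x += config.friction_amp * _chain_gain(chain, omega, angle) * env * rough

    # grade-dependent transient bursts: exponentially damped sinusoids
    grade = subject.icrs_grade
    rate = config.burst_rate_per_grade[grade]
    amp = config.burst_amp_per_grade[grade]
    burst_times: list[float] = []
    for t0_c, T in zip(starts, durations):
        for _ in range(rng.poisson(rate)):
            tb = t0_c + rng.uniform(0.0, T)
            f = rng.uniform(50.0, 400.0)
            tau = rng.uniform(0.010, 0.030)
            a = amp * rng.uniform(0.7, 1.3)
            phase = rng.uniform(0, 2 * np.pi)
            i0 = int(tb * fs)
            i1 = min(n, i0 + int(5 * tau * fs))
            if i0 >= n:
                continue
            tt = t[i0:i1] - tb
            x[i0:i1] += a * np.exp(-tt / tau) * np.sin(2 * np.pi * f * tt + phase)
            burst_times.append(tb)

    # sensor drift: integrated low-pass noise. The slope process is smoothed
    # on a scale exceeding one recording (~24 s), so the integrated drift is
    # trend-like (monotone or single-turn) and lands in the EMD residual.
    if config.drift_amp > 0:
        x += _drift_curve(rng, trace.total_duration, t, config.drift_amp)

    if config.hum_amp > 0:
        x += config.hum_amp * np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))

    # 10-bit ADC over full scale [-1, 1]
    full = 2**config.quant_bits - 1
    counts = np.clip(np.round((x + 1.0) / 2.0 * full), 0, full).astype(np.int32)

    return RawRecording(
        subject=subject, chain=chain, acoustic=counts, encoder=trace.angle,
        fs_acoustic=fs, fs_encoder=config.fs_encoder,
        quant_bits=config.quant_bits, knee=knee,
        truth={"burst_times": sorted(burst_times),
               "cycle_bounds": [list(b) for b in trace.cycle_bounds]},
    )


_DRIFT_FS = 4.0          # Hz, grid of the slow slope process
_DRIFT_SIGMA_S = 24.0    # s, smoothing scale of the slope process


def _drift_curve(rng: np.random.Generator, duration: float, t: np.ndarray,
                 amp: float) -> np.ndarray:
    """Integrated low-pass noise, scaled to peak amplitude ``amp``."""
    from scipy.interpolate import CubicSpline

    sigma = _DRIFT_SIGMA_S * _DRIFT_FS
    half = int(np.ceil(3 * sigma))
    n_slow = int(np.ceil(duration * _DRIFT_FS)) + 2
    w = rng.normal(size=n_slow + 2 * half)
    k = np.exp(-0.5 * ((np.arange(2 * half + 1) - half) / sigma) ** 2)
    slope = np.convolve(w, k / k.sum(), mode="valid")       # length n_slow
    walk = np.concatenate(([0.0], np.cumsum(slope[:-1]))) / _DRIFT_FS
    spline = CubicSpline(np.arange(n_slow) / _DRIFT_FS, walk)
    drift = spline(t)
    drift -= drift[0]
    return drift * (amp / max(np.abs(drift).max(), 1e-12))


def _sample_profile(group: Group, idx: int, config: GeneratorConfig) -> SubjectProfile:
    rng = _sub_rng(config.seed, 101 if group == Group.HC else 102, idx)
    age_m, age_s, h_m, h_s, w_m, w_s, p_male = DEMOGRAPHICS[group]
    age = float(rng.normal(age_m, age_s))
    height = float(max(rng.normal(h_m, h_s), 1.40))
    weight = float(max(rng.normal(w_m, w_s), 40.0))
    sex = Sex.M if rng.random() < p_male else Sex.F
    grade = 0 if group == Group.HC else int(rng.choice(config.oa_grades))
    return SubjectProfile(
        subject_id=f"{group.value}{idx:03d}", group=group, icrs_grade=grade,
        age=age, sex=sex, height=height, weight=weight,
        bmi=weight / height**2,
    )


@dataclass
class Cohort:
    profiles: list[SubjectProfile]
    recordings: list[RawRecording]

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "recording_id": r.recording_id,
                "subject_id": r.subject.subject_id,
                "group": r.subject.group.value,
                "icrs_grade": r.subject.icrs_grade,
                "age": r.subject.age,
                "sex": r.subject.sex.value,
                "bmi": r.subject.bmi,
                "chain": r.chain.value,
                "knee": r.knee,
            }
            for r in self.recordings
        ]
        return pd.DataFrame(rows)


def generate_profiles(config: GeneratorConfig) -> list[SubjectProfile]:
    """Demographics only (per-group normal age/height/weight, BMI derived)."""
    if config.n_hc < 1 or config.n_oa < 1:
        raise ValueError("n_hc and n_oa must both be >= 1")
    profiles = [_sample_profile(Group.HC, i, config) for i in range(config.n_hc)]
    profiles += [_sample_profile(Group.OA, i, config) for i in range(config.n_oa)]
    return profiles


def generate_cohort(config: GeneratorConfig,
                    chains: tuple[Chain, ...] = (Chain.OKC, Chain.CKC)) -> Cohort:
    """Full cohort: HC subjects contribute ``knees_per_hc`` recordings per chain,
    OA subjects one (the operated knee)."""
    profiles = generate_profiles(config)

    knee_tags = ["L", "R"]
    recordings: list[RawRecording] = []
    for prof in profiles:
        knees = (knee_tags[: config.knees_per_hc]
                 if prof.group == Group.HC else [knee_tags[0]])
        for knee in knees:
            for chain in chains:
                recordings.append(
                    generate_recording(prof, chain, config, config.seed, knee=knee))
    return Cohort(profiles=profiles, recordings=recordings)
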