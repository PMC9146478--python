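"""Core domain types shared across the pipeline.

A recording couples an acoustic channel (solid-body microphone on the
patella, 1400 Hz, 10-bit ADC counts) with a knee-angle channel (rotary
encoder, 10 Hz, hard stops at 0 and 90 degrees).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Any

import numpy as np


class Group(str, Enum):
    HC = "HC"
    OA = "OA"


class Chain(str, Enum):
    """Kinetic chain of the movement protocol.

    OKC: open kinetic chain (seated knee extension, distal segment free).
    CKC: closed kinetic chain (sit-to-stand, distal segment constrained).
    """

    OKC = "OKC"
    CKC = "CKC"


class Sex(str, Enum):
    M = "M"
    F = "F"


@dataclass(frozen=True)
class SubjectProfile:
    """One participant with intraoperative ICRS cartilage grade (0 = intact)."""

    subject_id: str
    group: Group
    icrs_grade: int
    age: float        # years
    sex: Sex
    height: float     # m
    weight: float     # kg
    bmi: float        # kg/m^2

    def __post_init__(self) -> None:
        if self.group == Group.HC and self.icrs_grade != 0:
            raise ValueError("HC subjects must have ICRS grade 0")
        if self.group == Group.OA and self.icrs_grade not in (1, 2, 3, 4):
            raise ValueError("OA subjects must have ICRS grade in 1..4")
        if abs(self.bmi - self.weight / self.height**2) > 1e-6:
            raise ValueError("bmi inconsistent with weight/height^2")


@dataclass(frozen=True)
class GeneratorConfig:
    """Synthetic-cohort settings.

    The acquisition constants mirror the hardware protocol the pipeline is
    designed for: 1400 Hz / 10-bit acoustic sampling, a 10 Hz encoder with
    0-90 degree hard stops, ~2 s 90-0-90 movement cycles, ten repetitions.
    Burst rate/amplitude are indexed by ICRS grade 0..4 and must be
    non-decreasing so that lesion severity maps to acoustic event energy.
    """

    n_hc: int = 33
    n_oa: int = 34
    seed: int = 0
    fs_acoustic: float = 1400.0
    fs_encoder: float = 10.0
    n_cycles: int = 10
    cycle_period: float = 2.0       # s per 90-0-90 excursion
    quant_bits: int = 10
    jitter: float = 0.1             # fractional per-cycle duration jitter
    idle_s: float = 1.0             # pre/post-motion rest at 90 degrees
    burst_rate_per_grade: tuple[float, ...] = (0.5, 2.0, 4.0, 6.0, 8.0)   # events/cycle
    burst_amp_per_grade: tuple[float, ...] = (0.04, 0.10, 0.22, 0.38, 0.55)  # rel. full scale
    drift_amp: float = 0.25         # rel. full scale, peak
    noise_std: float = 0.04         # broadband background, rel. full scale
    friction_amp: float = 0.08      # articular friction term, rel. full scale
    hum_amp: float = 0.01           # 50 Hz mains pickup, rel. full scale
    encoder_noise_deg: float = 0.1
    knees_per_hc: int = 2           # both knees recorded for controls
    oa_grades: tuple[int, ...] = (2, 3, 4)

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if len(self.burst_rate_per_grade) != 5 or len(self.burst_amp_per_grade) != 5:
            raise ValueError("burst parameters must cover grades 0..4")
        if any(b > a for a, b in zip(self.burst_rate_per_grade[1:],
                                     self.burst_rate_per_grade[:-1])):
            raise ValueError("burst_rate_per_grade must be non-decreasing in grade")
        # highest generated component: background-noise low-pass corner (600 Hz)
        if self.fs_acoustic <= 2 * 600.0:
            raise ValueError("fs_acoustic must exceed twice the highest component frequency")


@dataclass
class RawRecording:
    """Two-channel recording: quantized acoustic counts + encoder degrees.

    ``truth`` holds generator ground truth (injected burst times, cycle
    boundaries) for recordings produced by the synthetic cohort; it is empty
    for recordings read from external files that lack it.
    """

    subject: SubjectProfile
    chain: Chain
    acoustic: np.ndarray            # int counts on 2**quant_bits levels
    encoder: np.ndarray             # degrees in [0, 90] at fs_encoder
    fs_acoustic: float
    fs_encoder: float
    quant_bits: int = 10
    knee: str = ""                  # e.g. "L"/"R" for bilateral controls
    truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.acoustic = np.asarray(self.acoustic)
        self.encoder = np.asarray(self.encoder, dtype=float)
        if self.encoder.size and (self.encoder.min() < 0 or self.encoder.max() > 90):
            raise ValueError("encoder values must lie in [0, 90]")

    @property
    def recording_id(self) -> str:
        parts = [self.subject.subject_id]
        if self.knee:
            parts.append(self.knee)
        parts.append(self.chain.value)
        return "-".join(parts)

    def acoustic_float(self) -> np.ndarray:
        """Map ADC counts to the symmetric unit range [-1, 1]."""
        full = 2**self.quant_bits - 1
        return self.acoustic.astype(float) / full * 2.0 - 1.0
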