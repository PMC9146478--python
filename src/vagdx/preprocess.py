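"""Signal preprocessing: cycle cutting, EEMD denoising, detrending, scaling.

Stage order follows the acquisition protocol's cleaning recipe: (1) cut the
recording to the movement regime using slope detection on the encoder
channel, (2) decompose the trimmed acoustic signal with EEMD, (3) remove the
residual trend r(t) (sensor drift), (4) normalize amplitudes to [0, 1].

Cycle detection: a full cycle is a descent from >= 85 deg to <= 5 deg and a
return to >= 85 deg.  Anchors found by threshold crossing are refined to the
preceding/following slope break (where the backward/forward step falls under
0.5 deg), which lands the boundary on the hard-stop plateau edge.  A trace
whose largest per-sample step is below 2 deg per encoder period is treated
as motionless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Any

import numpy as np

from .emd import EEMDParams, IMFSet, eemd
from .types import RawRecording

logger = logging.getLogger(__name__)

HIGH_DEG = 85.0
LOW_DEG = 5.0
MOTION_THRESH_DEG = 2.0
SLOPE_BREAK_DEG = 0.5


class NoMovementError(ValueError):
    pass


class Direction(str, Enum):
    FLEXION = "flexion"
    EXTENSION = "extension"
    FULL_CYCLE = "full_cycle"


@dataclass(frozen=True)
class CycleSegment:
    """Half-open [start, end) acoustic-sample index range of one movement cycle."""

    start_index: int
    end_index: int
    direction: Direction = Direction.FULL_CYCLE

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ValueError("end_index must exceed start_index")


def _walk_to_slope_break(angle: np.ndarray, i: int, step: int) -> int:
    """From anchor i, walk in ``step`` direction while the angle keeps rising
    clearly (> SLOPE_BREAK_DEG per sample); stop at the peak/plateau edge."""
    j = i
    while 0 <= j + step < angle.size and angle[j + step] > angle[j] + SLOPE_BREAK_DEG:
        j += step
    return j


def detect_cycles(encoder: np.ndarray, fs_encoder: float,
                  fs_acoustic: float) -> list[CycleSegment]:
    """One full_cycle segment per 90-0-90 excursion, in acoustic sample indices."""
    angle = np.asarray(encoder, dtype=float)
    if angle.size < 3 or np.max(np.abs(np.diff(angle))) < MOTION_THRESH_DEG:
        logger.warning("no knee motion detected in encoder trace")
        return []
    low = angle <= LOW_DEG
    # maximal runs of low samples = cycle bottoms
    edges = np.diff(low.astype(int))
    run_starts = np.nonzero(edges == 1)[0] + 1
    run_ends = np.nonzero(edges == -1)[0] + 1   # exclusive
    if low[0]:
        run_starts = np.concatenate(([0], run_starts))
    if low[-1]:
        run_ends = np.concatenate((run_ends, [angle.size]))

    scale = fs_acoustic / fs_encoder
    segments: list[CycleSegment] = []
    prev_end = -1
    for rs, re in zip(run_starts, run_ends):
        before = np.nonzero(angle[:rs] >= HIGH_DEG)[0]
        after = np.nonzero(angle[re:] >= HIGH_DEG)[0]
        if before.size == 0 or after.size == 0:
            continue
        start = _walk_to_slope_break(angle, int(before[-1]), -1)
        end = _walk_to_slope_break(angle, int(re + after[0]), +1)
        if start < prev_end:     # segments may share the boundary sample
            start = prev_end
        if end <= start:
            continue
        segments.append(CycleSegment(start_index=int(round(start * scale)),
                                     end_index=int(round(end * scale))))
        prev_end = end
    return segments


def detrend(x: np.ndarray, decomp: IMFSet) -> np.ndarray:
    """Remove the decomposition's residual trend r(t) from x."""
    return np.asarray(x, dtype=float) - decomp.residual


def normalize01(x: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min); errors on a constant signal."""
    x = np.asarray(x, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi - lo == 0:
        raise ValueError("degenerate amplitude range: constant signal")
    return (x - lo) / (hi - lo)


@dataclass
class PreprocessResult:
    """Cleaned per-cycle signals, their concatenation, and a provenance log."""

    cycles: list[np.ndarray]
    concatenated: np.ndarray
    segments: list[CycleSegment]
    log: dict[str, Any] = field(default_factory=dict)


def preprocess_recording(rec: RawRecording, params: EEMDParams) -> PreprocessResult:
    """detect_cycles -> per-recording EEMD -> detrend -> normalize01."""
    segments = detect_cycles(rec.encoder, rec.fs_encoder, rec.fs_acoustic)
    if not segments:
        raise NoMovementError(
            f"{rec.recording_id}: no movement cycles found in encoder channel")
    x = rec.acoustic_float()
    start = segments[0].start_index
    end = min(segments[-1].end_index, x.size)
    trimmed = x[start:end]
    decomp = eemd(trimmed, params)
    cleaned = detrend(trimmed, decomp)
    cleaned = normalize01(cleaned)
    cycles = []
    for seg in segments:
        a = max(seg.start_index - start, 0)
        b = min(seg.end_index - start, cleaned.size)
        if b > a:
            cycles.append(cleaned[a:b])
    return PreprocessResult(
        cycles=cycles,
        concatenated=cleaned,
        segments=segments,
        log={
            "recording_id": rec.recording_id,
            "n_cycles": len(segments),
            "cycle_bounds_acoustic": [[s.start_index, s.end_index] for s in segments],
            "n_imfs": len(decomp.imfs),
            "n_trials": params.n_trials,
            "noise_std": params.noise_std,
        },
    )
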