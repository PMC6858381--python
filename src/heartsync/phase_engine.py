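"""Real-time cardiac phase assignment against a one-heartbeat reference.

Each incoming brightfield frame is scored against every frame of a reference
sequence spanning exactly one heartbeat, using a sum-of-absolute-differences
(SAD) metric

    s_phi = sum_xy | I_t(x, y) - R_phi(x + dx, y + dy) |

where (dx, dy) is the currently tracked in-plane sample drift.  The arg-min
of the score vector gives the integer phase, which is refined to sub-frame
precision by fitting a 'V' function to the three scores around the minimum.
The reference carries two padding frames at each end; these are excluded
from the initial minimum search (non-periodic content such as passing blood
cells can otherwise pin the minimum to an end frame) but their scores are
computed on demand when the minimum falls at an extremum.

Drift is tracked by a greedy hill-climb of the matched frame's score over
the 8-neighbourhood of integer pixel offsets; the updated offset is applied
to the *next* incoming frame, mirroring a real-time pipeline in which the
drift estimate always lags one frame.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import TWO_PI, vfit_min_offset
from .errors import InputFormatError

__all__ = [
    "Frame",
    "ReferenceSequence",
    "DriftOffset",
    "PhaseEstimate",
    "sad_score_vector",
    "match_phase",
    "update_drift",
]


@dataclass(frozen=True)
class Frame:
    """One time-stamped grayscale image from the brightfield stream."""

    pixels: np.ndarray
    timestamp: float
    index: int

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim != 2:
            raise InputFormatError(f"frame {self.index}: pixels must be 2-D, got shape {p.shape}")
        if not np.all(np.isfinite(p)):
            raise InputFormatError(f"frame {self.index}: non-finite pixel values")


@dataclass(frozen=True)
class DriftOffset:
    """Integer in-plane sample translation (dx = columns, dy = rows)."""

    dx: int = 0
    dy: int = 0

    def as_tuple(self):
        return (self.dx, self.dy)


@dataclass
class ReferenceSequence:
    """Exactly one heartbeat of frames, padded by two extra frames at each end.

    ``frames`` are the core one-period frames; ``period_frames`` is the
    (possibly fractional) number of stream frames per heartbeat;
    ``barrier_frame`` indexes the core frame marking the end of the
    inter-beat refractory period.
    """

    frames: list
    pad_before: list
    pad_after: list
    period_frames: float
    barrier_frame: int
    acquired_at: float
    sequence_id: int = 0
    drift_origin: DriftOffset = field(default_factory=DriftOffset)
    _stack: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if len(self.pad_before) != 2 or len(self.pad_after) != 2:
            raise InputFormatError("reference sequence requires exactly 2 padding frames at each end")
        if not self.frames:
            raise InputFormatError("reference sequence has no core frames")
        if not (0 <= self.barrier_frame < len(self.frames)):
            raise InputFormatError("barrier_frame outside the core sequence")
        if not self.period_frames > 0:
            raise InputFormatError("period_frames must be positive")

    def __len__(self):
        return len(self.frames)

    @property
    def stack(self) -> np.ndarray:
        """Core frames as a float32 (n, H, W) array (cached)."""
        if self._stack is None:
            self._stack = np.stack([np.asarray(f.pixels, dtype=np.float32) for f in self.frames])
        return self._stack

    @property
    def frame_rate(self) -> float:
        ts = [f.timestamp for f in self.frames]
        if len(ts) > 1:
            return (len(ts) - 1) / (ts[-1] - ts[0])
        return 1.0


@dataclass
class PhaseEstimate:
    """Integer best-match index plus sub-frame offset, as radians in [0, 2pi)."""

    best_index: int
    subframe_offset: float
    phase_radians: float
    scores: np.ndarray
    timestamp: float
    degenerate: bool = False


def _overlap_windows(shape, drift: DriftOffset):
    """Index windows of frame and (drift-shifted) reference that overlap.

    The comparison region is I[y, x] against R[y + dy, x + dx], restricted to
    indices valid in both images.
    """
    h, w = shape
    dx, dy = drift.dx, drift.dy
    if abs(dx) >= w or abs(dy) >= h:
        raise InputFormatError(f"drift ({dx}, {dy}) leaves no overlap for image shape {shape}")
    y0, y1 = max(0, -dy), min(h, h - dy)
    x0, x1 = max(0, -dx), min(w, w - dx)
    frame_win = (slice(y0, y1), slice(x0, x1))
    ref_win = (slice(y0 + dy, y1 + dy), slice(x0 + dx, x1 + dx))
    return frame_win, ref_win


def sad_score_vector(frame: Frame, ref: ReferenceSequence, drift: DriftOffset = DriftOffset()) -> np.ndarray:
    """SAD score of ``frame`` against every non-padding reference frame."""
    pix = np.asarray(frame.pixels, dtype=np.float32)
    if pix.shape != ref.stack.shape[1:]:
        raise InputFormatError(f"frame shape {pix.shape} != reference shape {ref.stack.shape[1:]}")
    fwin, rwin = _overlap_windows(pix.shape, drift)
    window = pix[fwin]
    refs = ref.stack[(slice(None),) + rwin]
    return np.abs(refs - window[None]).sum(axis=(1, 2))


def _pad_score(frame: Frame, pad_frame: Frame, drift: DriftOffset) -> float:
    pix = np.asarray(frame.pixels, dtype=np.float32)
    fwin, rwin = _overlap_windows(pix.shape, drift)
    ref = np.asarray(pad_frame.pixels, dtype=np.float32)
    return float(np.abs(ref[rwin] - pix[fwin]).sum())


def match_phase(
    s: np.ndarray,
    ref: ReferenceSequence,
    frame: Frame | None = None,
    drift: DriftOffset = DriftOffset(),
) -> PhaseEstimate:
    """Arg-min phase with sub-frame V refinement.

    ``s`` must cover all non-padding frames.  Ties break to the lowest index.
    When the minimum sits at either extremum the adjacent padding frame's
    score is computed on demand (``frame`` must then be supplied; without it
    the cyclic neighbour within the core is used as a fallback).
    """
    s = np.asarray(s, dtype=float)
    n = len(ref.frames)
    if s.shape != (n,):
        raise InputFormatError(f"score vector length {s.shape} != core length {n}")
    i = int(np.argmin(s))

    if i > 0:
        s_left = s[i - 1]
    elif frame is not None:
        s_left = _pad_score(frame, ref.pad_before[1], drift)
    else:
        s_left = s[-1]
    if i < n - 1:
        s_right = s[i + 1]
    elif frame is not None:
        s_right = _pad_score(frame, ref.pad_after[0], drift)
    else:
        s_right = s[0]

    off, degen = vfit_min_offset(float(s_left), float(s[i]), float(s_right))
    phase = TWO_PI * ((i + off) % ref.period_frames) / ref.period_frames
    if phase >= TWO_PI:  # guard the wrap boundary against float round-off
        phase -= TWO_PI
    ts = frame.timestamp if frame is not None else float("nan")
    return PhaseEstimate(i, off, phase, s, ts, degen)


def mean_sad(frame_pixels: np.ndarray, ref_pixels: np.ndarray, drift: DriftOffset) -> float:
    """Per-pixel mean absolute difference over the drift overlap window.

    Used for drift search, where candidate offsets have different overlap
    areas and the raw SAD sum would be biased toward smaller windows.
    """
    pix = np.asarray(frame_pixels, dtype=np.float32)
    fwin, rwin = _overlap_windows(pix.shape, drift)
    diff = np.abs(np.asarray(ref_pixels, dtype=np.float32)[rwin] - pix[fwin])
    return float(diff.mean())


def update_drift(
    frame: Frame,
    ref: ReferenceSequence,
    estimate: PhaseEstimate,
    drift: DriftOffset,
    max_steps: int = 10,
) -> DriftOffset:
    """Greedy hill-climb of the matched frame's score over pixel offsets.

    Iterates over the 8-neighbourhood until a local minimum or ``max_steps``
    moves; the returned offset is meant to be applied to the *next* frame.
    Offsets are bounded to a quarter of the image size in each axis.
    """
    ref_pix = ref.stack[estimate.best_index]
    h, w = ref_pix.shape
    bx, by = max(1, w // 4), max(1, h // 4)
    cur = drift
    cur_score = mean_sad(frame.pixels, ref_pix, cur)
    for _ in range(max_steps):
        best, best_score = cur, cur_score
        for ddx in (-1, 0, 1):
            for ddy in (-1, 0, 1):
                if ddx == 0 and ddy == 0:
                    continue
                cand = DriftOffset(cur.dx + ddx, cur.dy + ddy)
                if abs(cand.dx) > bx or abs(cand.dy) > by:
                    continue
                sc = mean_sad(frame.pixels, ref_pix, cand)
                if sc < best_score:
                    best, best_score = cand, sc
        if best == cur:
            break
        cur, cur_score = best, best_score
    return cur
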