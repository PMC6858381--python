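"""Absolute phase alignment of reference heartbeat sequences.

Maintaining a fixed phase-lock across reference refreshes requires knowing
the *absolute* phase shift of every reference sequence relative to the first
one.  Pairwise shifts between resampled one-heartbeat sequences are measured
by cyclic cross-correlation along the phase axis (computed in Fourier space;
equivalent at the optimum to minimising the least-squares image-difference
criterion, since cyclic shifting preserves the energy terms), refined to
sub-sample precision by V-fitting the correlation peak.  Each pairwise shift
is only known modulo 2*pi, so a naive least-squares solve of the
over-determined system A x = r (rows a -> b with coefficients -1, +1) is
inconsistent whenever accumulated shifts wrap.  The multi-pass solver first
restricts the system to temporally adjacent pairs (dt_max = 1), solves,
re-wraps every measured shift onto the current solution by adding integer
multiples of 2*pi, and repeats with gradually increasing dt_max until all
pairs are used.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import TWO_PI, wrap_to_pm_pi, wrap_to_2pi
from .errors import AlignmentError, ParameterError
from .phase_engine import DriftOffset, ReferenceSequence

__all__ = [
    "ResampledSequence",
    "RelativeShift",
    "GlobalAlignment",
    "AlignmentConfig",
    "AlignmentState",
    "resample_sequence",
    "relative_shift",
    "multipass_align",
    "refresh_reference",
]


@dataclass
class ResampledSequence:
    """One heartbeat resampled to exactly L frames uniformly over the cycle."""

    frames: np.ndarray  # (L, H, W) float32
    source_id: int
    source_drift_origin: DriftOffset = field(default_factory=DriftOffset)
    period_frames: float = 0.0

    @property
    def L(self) -> int:
        return self.frames.shape[0]


@dataclass
class RelativeShift:
    """Wrapped pairwise phase shift between sequences a and b (a < b).

    ``dphi`` in (-pi, pi] models x_b - x_a; ``weight`` enters the global
    least-squares regression.
    """

    a: int
    b: int
    dphi: float
    weight: float = 1.0

    def __post_init__(self):
        if not self.a < self.b:
            raise ParameterError("RelativeShift requires a < b")
        if not (-np.pi < self.dphi <= np.pi):
            raise ParameterError("dphi must be wrapped to (-pi, pi]")
        if self.weight <= 0:
            raise ParameterError("weight must be positive")


@dataclass
class GlobalAlignment:
    """Absolute (unwrapped) shift per sequence id, gauge-fixed x[first] = 0."""

    ids: list
    x: np.ndarray
    residuals: np.ndarray

    def shift_of(self, seq_id: int) -> float:
        return float(self.x[self.ids.index(seq_id)])


@dataclass
class AlignmentConfig:
    L: int = 80
    max_pairings: int = 3
    dt_schedule: tuple = (1, 3)
    weighting: str = "uniform"  # "uniform" | "sharpness"

    def __post_init__(self):
        if self.L < 4:
            raise ParameterError("resample length L must be >= 4")
        if self.weighting not in ("uniform", "sharpness"):
            raise ParameterError("weighting must be 'uniform' or 'sharpness'")


def resample_sequence(ref: ReferenceSequence, L: int) -> ResampledSequence:
    """Pixelwise linear interpolation at L uniform phase points over one cycle.

    Sample j sits at frame coordinate j * period_frames / L in the cyclic
    time coordinate of the core frames, interpolated between its bracketing
    frames; the final segment (from frame n-1 back to frame 0) spans the
    fractional remainder period_frames - (n - 1), keeping the resampled
    phase axis consistent with the 2*pi * i / period_frames convention used
    for per-frame phase estimates.
    """
    if L < 4:
        raise ParameterError("resample length L must be >= 4")
    stack = ref.stack
    n = stack.shape[0]
    period = float(ref.period_frames)
    pos = np.arange(L) * (period / L)
    frames = np.empty((L,) + stack.shape[1:], dtype=np.float32)
    interior = pos < n - 1
    i0 = np.floor(pos[interior]).astype(int)
    frac = (pos[interior] - i0).astype(np.float32)[:, None, None]
    frames[interior] = (1.0 - frac) * stack[i0] + frac * stack[i0 + 1]
    tail = ~interior
    if tail.any():
        seg = max(period - (n - 1), 1e-9)
        frac_t = ((pos[tail] - (n - 1)) / seg).astype(np.float32)
        frac_t = np.clip(frac_t, 0.0, 1.0)[:, None, None]
        frames[tail] = (1.0 - frac_t) * stack[n - 1] + frac_t * stack[0]
    return ResampledSequence(
        frames=frames.astype(np.float32),
        source_id=ref.sequence_id,
        source_drift_origin=ref.drift_origin,
        period_frames=ref.period_frames,
    )


def _phase_correlation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """corr[s] = sum_phi sum_xy A[phi] * B[phi + s], via FFT along phase."""
    L = A.shape[0]
    fa = np.fft.rfft(A, axis=0)
    fb = np.fft.rfft(B, axis=0)
    return np.fft.irfft(np.conj(fa) * fb, n=L, axis=0).sum(axis=(1, 2))


def relative_shift(A: ResampledSequence, B: ResampledSequence, dx: int = 0, dy: int = 0) -> RelativeShift:
    """Wrapped phase shift of sequence B relative to A.

    (dx, dy) is the in-plane translation of the sample between the two
    acquisition times, as recorded by the drift tracker; B is un-translated
    before correlation.  The integer arg-max of the cyclic cross-correlation
    is refined by V-fitting, and dphi = 2*pi*shift/L wrapped to (-pi, pi].
    """
    if A.frames.shape != B.frames.shape:
        raise ParameterError(f"sequence shapes differ: {A.frames.shape} vs {B.frames.shape}")
    Bs = B.frames
    if dx or dy:
        # compare A(x, y) with B(x + dx, y + dy): shift B back onto A's window
        Bs = np.roll(Bs, shift=(-dy, -dx), axis=(1, 2))
    corr = _phase_correlation(A.frames, Bs)
    L = corr.shape[0]
    k = int(np.argmax(corr))
    c_l, c0, c_r = float(corr[(k - 1) % L]), float(corr[k]), float(corr[(k + 1) % L])
    # Parabolic peak interpolation: the cyclic correlation of smoothly
    # resampled sequences has a locally quadratic maximum, for which the
    # three-point parabola is the exact sub-sample interpolator (the 'V'
    # model instead matches the piecewise-linear absolute-difference score
    # used for per-frame phase matching).
    denom = c_l - 2.0 * c0 + c_r
    off = 0.0 if denom == 0.0 else float(np.clip(0.5 * (c_l - c_r) / denom, -0.5, 0.5))
    shift = k + off
    dphi = wrap_to_pm_pi(TWO_PI * shift / L)
    if A.source_id < B.source_id:
        a, b = A.source_id, B.source_id
    else:
        a, b = B.source_id, A.source_id
        dphi = wrap_to_pm_pi(-dphi)
    weight = 1.0
    rng_c = float(corr.max() - corr.min())
    if rng_c > 0:
        sharp = float(corr[k] - 0.5 * (c_l + c_r)) / rng_c
        weight = max(sharp, 1e-3)
    return RelativeShift(a=a, b=b, dphi=float(dphi), weight=weight)


def _check_connected(ids, shifts):
    parent = {i: i for i in ids}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for s in shifts:
        ra, rb = find(s.a), find(s.b)
        if ra != rb:
            parent[ra] = rb
    roots = {find(i) for i in ids}
    if len(roots) > 1:
        comp0 = find(ids[0])
        unreachable = sorted(i for i in ids if find(i) != comp0)
        raise AlignmentError(f"shift graph is disconnected; unreachable sequence ids: {unreachable}")


def _solve_gauge_fixed(shifts, ids, idx, r, use_rows):
    """Weighted least squares of A x = r over selected rows, with x[first] = 0."""
    n = len(ids)
    rows = np.flatnonzero(use_rows)
    Amat = np.zeros((len(rows), n - 1))
    rhs = np.empty(len(rows))
    for out_i, i in enumerate(rows):
        s = shifts[i]
        w = np.sqrt(s.weight)
        ia, ib = idx[s.a], idx[s.b]
        if ia > 0:
            Amat[out_i, ia - 1] = -w
        if ib > 0:
            Amat[out_i, ib - 1] = w
        rhs[out_i] = w * r[i]
    sol, *_ = np.linalg.lstsq(Amat, rhs, rcond=None)
    return np.concatenate(([0.0], sol))


def multipass_align(shifts, dt_schedule=(1, 3)) -> GlobalAlignment:
    """Solve for absolute shifts with the multi-pass modular least squares.

    Each pass restricts the system to pairs with b - a <= dt_max, solves the
    gauge-fixed weighted least squares, then re-wraps the *full* measurement
    vector r onto the solution by adding integer multiples of 2*pi.  A final
    pass uses all pairs.  Raises AlignmentError when the pair graph does not
    connect all sequence ids.
    """
    shifts = list(shifts)
    if not shifts:
        raise AlignmentError("no relative shifts supplied")
    ids = sorted({s.a for s in shifts} | {s.b for s in shifts})
    _check_connected(ids, shifts)
    idx = {sid: i for i, sid in enumerate(ids)}
    r = np.array([s.dphi for s in shifts], dtype=float)
    gaps = np.array([s.b - s.a for s in shifts])
    x = np.zeros(len(ids))
    passes = [dt for dt in dt_schedule] + [int(gaps.max())]
    for dt_max in passes:
        use = gaps <= dt_max
        if not use.any():
            continue
        x = _solve_gauge_fixed(shifts, ids, idx, r, use)
        model = np.array([x[idx[s.b]] - x[idx[s.a]] for s in shifts])
        r += TWO_PI * np.round((model - r) / TWO_PI)
    model = np.array([x[idx[s.b]] - x[idx[s.a]] for s in shifts])
    return GlobalAlignment(ids=ids, x=x, residuals=r - model)


class AlignmentState:
    """Running alignment history across reference refreshes.

    Keeps the resampled form of the most recent ``max_pairings`` sequences,
    every pairwise shift measured so far, the current global solution, and
    the user target phase expressed in sequence 0 (``target0``).
    """

    def __init__(self, first_ref: ReferenceSequence, target_phase: float, config: AlignmentConfig | None = None):
        self.config = config or AlignmentConfig()
        self.target0 = float(target_phase)
        self.shifts: list[RelativeShift] = []
        self.recent: list[ResampledSequence] = [resample_sequence(first_ref, self.config.L)]
        self.alignment: GlobalAlignment | None = None
        self.n_sequences = 1

    def register_unaligned(self, ref: ReferenceSequence):
        """Record a sequence without alignment (used after a failed refresh)."""
        self.recent.append(resample_sequence(ref, self.config.L))
        self.recent = self.recent[-self.config.max_pairings :]
        self.n_sequences += 1


def refresh_reference(state: AlignmentState, new_ref: ReferenceSequence, old_target_phase: float):
    """Re-anchor the target phase in a freshly acquired reference sequence.

    Resamples ``new_ref``, measures wrapped shifts against up to
    ``max_pairings`` recent sequences (correcting for the drift recorded
    between their acquisitions), re-solves the global alignment, and maps the
    sequence-0 target phase into the new sequence:
    new_target = wrap(target0 + (x_new - x_0)).  On alignment failure the
    caller should retain ``old_target_phase``; the error propagates.
    """
    new_rs = resample_sequence(new_ref, state.config.L)
    if not state.recent:
        raise AlignmentError("alignment state holds no prior sequence")
    new_shifts = []
    for past in state.recent[-state.config.max_pairings :]:
        dx = new_rs.source_drift_origin.dx - past.source_drift_origin.dx
        dy = new_rs.source_drift_origin.dy - past.source_drift_origin.dy
        sh = relative_shift(past, new_rs, dx, dy)
        if state.config.weighting == "uniform":
            sh.weight = 1.0
        new_shifts.append(sh)
    shifts = state.shifts + new_shifts
    alignment = multipass_align(shifts, state.config.dt_schedule)
    x_new = alignment.shift_of(new_rs.source_id)
    x_0 = alignment.x[0]
    new_target = wrap_to_2pi(state.target0 + (x_new - x_0))
    state.shifts = shifts
    state.alignment = alignment
    state.recent.append(new_rs)
    state.recent = state.recent[-state.config.max_pairings :]
    state.n_sequences += 1
    return float(new_target), state
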