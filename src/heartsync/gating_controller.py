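"""Reference acquisition, barrier-frame estimation, trigger forward-prediction
and the one-triggered-frame-per-plane time-lapse loop.

The controller watches the brightfield stream, assigns a phase to every frame
(phase_engine), and forward-predicts when the heart will next reach the target
phase by a linear fit of the recent unwrapped phase history.  The fit is
restricted to frames received since the barrier frame — the reference index
marking the end of the inter-beat refractory period — was last passed, because
the refractory interval's duration varies from beat to beat and a fit spanning
it extrapolates badly.  A trigger is committed only when the predicted time is
close enough (one frame interval plus the processing latency) that waiting for
the next frame would not improve it.

At regular intervals (by default after each z-stack) the reference sequence is
refreshed and re-anchored to the running global alignment
(sequence_alignment.refresh_reference) so that phase-lock survives the slow
morphological change of the developing heart.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import TWO_PI, wrap_to_pm_pi, vfit_min_offset
from .errors import AcquisitionError, GatingError, ParameterError
from .phase_engine import (
    DriftOffset,
    Frame,
    ReferenceSequence,
    match_phase,
    mean_sad,
    sad_score_vector,
    update_drift,
)

__all__ = [
    "PhaseHistory",
    "TriggerDecision",
    "GatingConfig",
    "TriggerRecord",
    "estimate_period_frames",
    "acquire_reference",
    "estimate_barrier_frame",
    "predict_trigger_time",
    "run_timelapse",
]


@dataclass
class PhaseHistory:
    """Recent (timestamp, unwrapped phase) pairs plus barrier-crossing times."""

    timestamps: list = field(default_factory=list)
    phases: list = field(default_factory=list)
    barrier_crossings: list = field(default_factory=list)
    max_len: int = 400

    def append(self, t: float, phase_unwrapped: float):
        if self.timestamps and t <= self.timestamps[-1]:
            raise ParameterError("history timestamps must be strictly increasing")
        self.timestamps.append(t)
        self.phases.append(phase_unwrapped)
        if len(self.timestamps) > self.max_len:
            del self.timestamps[0], self.phases[0]

    def clear(self):
        self.timestamps.clear()
        self.phases.clear()
        self.barrier_crossings.clear()

    def __len__(self):
        return len(self.timestamps)


@dataclass
class TriggerDecision:
    action: str  # "commit" | "wait" | "skip_beat"
    trigger_time: float | None
    predicted_rate: float


@dataclass
class GatingConfig:
    """Controller parameters.

    ``latency`` is the processing delay from brightfield exposure to trigger
    programming (default 12 ms); ``frame_interval`` the brightfield frame
    spacing (default 1/80 s); ``fit_mode`` selects barrier-restricted linear
    fitting (default) or a fixed-length window (``fixed_window_points``
    entries) for the ablation comparison.
    """

    target_phase: float = 0.0
    latency: float = 0.012
    frame_interval: float = 1.0 / 80.0
    refresh_every: str = "per_stack"  # "per_stack" | "never" | "every_n_planes"
    refresh_n_planes: int = 0
    min_fit_points: int = 3
    fit_mode: str = "barrier"  # "barrier" | "fixed"
    fixed_window_points: int = 30

    def __post_init__(self):
        if self.latency < 0:
            raise ParameterError("latency must be >= 0")
        if not (0.0 <= self.target_phase < TWO_PI):
            raise ParameterError("target_phase must lie in [0, 2pi)")
        if self.fit_mode not in ("barrier", "fixed"):
            raise ParameterError("fit_mode must be 'barrier' or 'fixed'")


@dataclass
class TriggerRecord:
    timepoint: int
    plane: int
    trigger_time: float
    target_phase: float
    predicted_rate: float
    sequence_id: int
    drift: tuple
    realized_phase: float | None = None
    frames_processed: int = 0


def _self_similarity(frames, start: int, max_lag: int) -> np.ndarray:
    base = frames[start].pixels
    zero = DriftOffset()
    return np.array([mean_sad(base, frames[start + lag].pixels, zero) for lag in range(1, max_lag + 1)])


def _motion_trace(frames) -> np.ndarray:
    zero = DriftOffset()
    return np.array(
        [mean_sad(frames[i].pixels, frames[i + 1].pixels, zero) for i in range(len(frames) - 1)]
    )


def _trace_period(m: np.ndarray):
    """Integer period estimate from the autocorrelation of the adjacent-frame
    motion trace.  The trace spikes once per contraction, so its first strong
    autocorrelation peak cannot alias onto a fraction of the beat the way
    image self-similarity can.  Returns None when no usable peak exists."""
    x = m - m.mean()
    n = len(x)
    kmin = 4
    if n < 3 * kmin:
        return None
    r = np.correlate(x, x, "full")[n - 1 :]
    if r[0] <= 0:
        return None
    hi = 2 * n // 3
    if hi <= kmin:
        return None
    k = kmin + int(np.argmax(r[kmin:hi]))
    # step down the harmonic ladder: a comparable peak at half the lag means
    # k caught a multiple of the true period
    while k >= 2 * kmin:
        kh = int(round(k / 2))
        lo2, hi2 = max(kmin, kh - 2), min(hi, kh + 3)
        kh_best = lo2 + int(np.argmax(r[lo2:hi2]))
        if r[kh_best] >= 0.6 * r[k]:
            k = kh_best
        else:
            break
    if r[k] <= 0.1 * r[0]:
        return None
    return int(k)


def _vee_apex(v: np.ndarray, j: int, halfwidth: int = 3) -> float:
    """Apex (in v-index units) of an asymmetric V through the samples around j.

    The recurrence dip generally has unequal slopes (the forward lag runs
    into the fast contraction, the backward lag into slower motion), so the
    symmetric V-fit is biased; fit c + a*max(x0-x, 0) + b*max(x-x0, 0) over a
    small window with a grid search on the apex x0 instead.
    """
    lo = max(0, j - halfwidth)
    hi = min(len(v), j + halfwidth + 1)
    xs = np.arange(lo, hi, dtype=float)
    ys = v[lo:hi]
    if len(xs) < 4:
        return float(j)
    best = (np.inf, float(j))
    for x0 in np.arange(j - 1.0, j + 1.0 + 1e-9, 0.02):
        X = np.column_stack([np.ones_like(xs), np.maximum(x0 - xs, 0.0), np.maximum(xs - x0, 0.0)])
        coef, res, *_ = np.linalg.lstsq(X, ys, rcond=None)
        sse = float(((X @ coef - ys) ** 2).sum())
        if sse < best[0]:
            best = (sse, float(x0))
    return best[1]


def estimate_period_frames(frames, start: int | None = None) -> tuple:
    """Heartbeat period (in frames, sub-frame precision) by image self-similarity.

    The beat length is first bracketed from the autocorrelation of the
    adjacent-frame motion trace (robust: one contraction spike per beat),
    then pinned to the image self-similarity minimum of a high-motion start
    frame within +-25% of that lag, and refined to sub-frame precision by
    V-fitting.  Returns (period_frames, start_index).
    """
    frames = list(frames)
    n = len(frames)
    if n < 8:
        raise AcquisitionError("stream too short for period determination")
    m = _motion_trace(frames)
    if float(m.max()) - float(m.min()) <= 1e-12 * max(float(m.max()), 1.0):
        raise AcquisitionError("no periodic recurrence found (static scene)")
    if start is None:
        lo, hi = 2, max(3, n // 3)
        start = lo + int(np.argmax(m[lo:hi]))
    max_lag = n - start - 3
    if max_lag < 4:
        raise AcquisitionError("stream too short after chosen start frame")
    v = _self_similarity(frames, start, max_lag)
    vmin, vmax = float(v.min()), float(v.max())
    if vmax - vmin <= 1e-12 * max(vmax, 1.0):
        raise AcquisitionError("no periodic recurrence found (flat self-similarity)")
    k0 = _trace_period(m)
    if k0 is not None and int(0.75 * k0) <= max_lag:
        lo_lag = max(2, int(np.floor(0.75 * k0)))
        hi_lag = min(max_lag, int(np.ceil(1.25 * k0)))
        if hi_lag <= lo_lag:
            raise AcquisitionError("search band for the recurrence minimum is empty")
        j = (lo_lag - 1) + int(np.argmin(v[lo_lag - 1 : hi_lag]))  # v[j] is the score at lag j+1
    else:
        # short-window fallback: deepest minimum after the initial rise
        hi_thr = vmin + 0.6 * (vmax - vmin)
        risen = np.flatnonzero(v >= hi_thr)
        if len(risen) == 0:
            raise AcquisitionError("no periodic recurrence found within the search window")
        j = risen[0] + int(np.argmin(v[risen[0] :]))
    if v[j] > vmin + 0.5 * (vmax - vmin):
        raise AcquisitionError("no convincing recurrence minimum in the search band")
    if v[j] <= 1e-9 * vmax:
        return float(j + 1), start  # exact recurrence: no sub-frame part
    return float(_vee_apex(v, j) + 1), start


def estimate_mean_period_frames(frames, start: int | None = None, expected_period: float | None = None) -> float:
    """Mean heartbeat period over a window, from the full ladder of
    self-similarity recurrence minima.

    Where :func:`estimate_period_frames` measures the lag to the *first*
    recurrence (one specific beat), this collects every deep recurrence
    minimum across the window — lags near P, 2P, 3P, ... — V-fits each to
    sub-frame precision and least-squares fits lag_j ~ j * P, averaging the
    beat-to-beat jitter away.  Used for heart-rate measurement.

    ``expected_period`` (frames), e.g. from the previous measurement, seeds
    the ladder spacing directly; without it the cross-checked single-beat
    estimate is used.
    """
    frames = list(frames)
    n = len(frames)
    if n < 8:
        raise AcquisitionError("stream too short for period determination")
    if start is None:
        zero = DriftOffset()
        lo, hi = 2, max(3, n // 3)
        motion = [mean_sad(frames[i].pixels, frames[i + 1].pixels, zero) for i in range(lo, hi)]
        start = lo + int(np.argmax(motion))
    max_lag = n - start - 3
    if max_lag < 4:
        raise AcquisitionError("stream too short after chosen start frame")
    v = _self_similarity(frames, start, max_lag)
    vmin, vmax = float(v.min()), float(v.max())
    if vmax - vmin <= 1e-12 * max(vmax, 1.0):
        raise AcquisitionError("no periodic recurrence found (flat self-similarity)")
    # seed the ladder so an aliased pseudo-recurrence cannot set the rung
    # spacing: either from the caller's expectation (continuity with the
    # previous measurement) or from the cross-checked single-beat estimate
    if expected_period is not None:
        p1 = float(expected_period)
    else:
        p1, _ = estimate_period_frames(frames, start=start)
    # walk the recurrence ladder: each next minimum is searched in a +-30%
    # band around one period past the previous one, so beat-to-beat jitter
    # cannot derail the beat count
    ks, lags = [], []
    prev_lag = 0.0
    mid_thr = vmin + 0.5 * (vmax - vmin)
    for k in range(1, int(max_lag / p1) + 2):
        lo = max(1, int(np.floor(prev_lag + 0.7 * p1)))
        hi = int(np.ceil(prev_lag + 1.3 * p1))
        if hi > max_lag:
            break  # band clipped by the window end: stop rather than latch a false rung
        seg = v[lo - 1 : hi]  # v[j] is the score at lag j+1
        j = lo + int(np.argmin(seg))
        if v[j - 1] > mid_thr:
            break  # recurrence has washed out
        if v[j - 1] <= 1e-9 * vmax:
            off = 0.0
        elif 1 < j < max_lag:
            off, _ = vfit_min_offset(float(v[j - 2]), float(v[j - 1]), float(v[j]))
        else:
            off = 0.0
        lag = j + off
        ks.append(float(k))
        lags.append(lag)
        prev_lag = lag
    if not lags:
        raise AcquisitionError("no recurrence minima found")
    ks, lags = np.array(ks), np.array(lags)
    return float((ks * lags).sum() / (ks * ks).sum())


def acquire_reference(stream, sequence_id: int = 0, drift_origin: DriftOffset = DriftOffset()) -> ReferenceSequence:
    """Extract one heartbeat (plus 2 padding frames at each end) from a stream.

    The stream must cover at least two heartbeats.  The period is found by
    self-similarity; the core sequence starts at the chosen high-motion start
    frame and spans round(period) frames; the barrier frame is estimated from
    the adjacent-frame motion metric.
    """
    frames = list(stream)
    period, start = estimate_period_frames(frames)
    n_core = int(round(period))
    if n_core < 4:
        raise AcquisitionError(f"period of {period:.2f} frames is too short for a reference")
    if start < 2 or start + n_core + 2 > len(frames):
        # shift the window so the pads fit; period estimate is unaffected
        start = max(2, min(start, len(frames) - n_core - 2))
        if start < 2 or start + n_core + 2 > len(frames):
            raise AcquisitionError("stream too short to pad the reference sequence")
    core = frames[start : start + n_core]
    ref = ReferenceSequence(
        frames=core,
        pad_before=frames[start - 2 : start],
        pad_after=frames[start + n_core : start + n_core + 2],
        period_frames=period,
        barrier_frame=0,
        acquired_at=core[0].timestamp,
        sequence_id=sequence_id,
        drift_origin=drift_origin,
    )
    ref.barrier_frame = estimate_barrier_frame(ref)
    return ref


def adjacent_motion(ref: ReferenceSequence) -> np.ndarray:
    """Cyclic adjacent-frame SAD motion metric v_phi over the core frames."""
    stack = ref.stack
    nxt = np.roll(stack, -1, axis=0)
    return np.abs(nxt - stack).sum(axis=(1, 2))


def estimate_barrier_frame(ref: ReferenceSequence) -> int:
    """Barrier frame: end of the refractory period within the reference.

    Finds the minimal-motion frame (refractory), then searches forward
    cyclically for the first frame whose motion reaches the half-range
    threshold (max v + min v) / 2.  A flat metric falls back to the
    minimal-motion index itself.
    """
    if len(ref.frames) < 4:
        raise ParameterError("reference must have at least 4 frames")
    v = adjacent_motion(ref)
    n = len(v)
    m = int(np.argmin(v))
    thr = 0.5 * (float(v.max()) + float(v.min()))
    for k in range(n):
        idx = (m + k) % n
        if v[idx] >= thr:
            return idx
    return m


def _fit_entries(history: PhaseHistory, config: GatingConfig):
    t = np.asarray(history.timestamps)
    p = np.asarray(history.phases)
    if config.fit_mode == "fixed":
        k = max(config.min_fit_points, config.fixed_window_points)
        return t[-k:], p[-k:]
    if history.barrier_crossings:
        last = history.barrier_crossings[-1]
        sel = t > last
        if sel.sum() >= config.min_fit_points:
            return t[sel], p[sel]
    k = config.min_fit_points
    return t[-k:], p[-k:]


def predict_trigger_time(
    history: PhaseHistory, ref: ReferenceSequence, config: GatingConfig, now: float
) -> TriggerDecision:
    """Forward-extrapolate the phase history to the next target-phase crossing.

    Least-squares line fit of unwrapped phase vs time over entries since the
    last barrier crossing (always at least ``min_fit_points`` entries); the
    trigger lands at now + dphi/omega where dphi is the forward wrapped
    distance to the target.  Commit iff that lies within one frame interval
    plus the latency; an unreachable target (inside the latency window) is
    deferred by one fitted period (skip_beat).
    """
    if len(history) == 0:
        raise ParameterError("history is empty")
    t, p = _fit_entries(history, config)
    if len(t) < 2:
        return TriggerDecision("wait", None, 0.0)
    t0 = t[-1]
    slope, intercept = np.polyfit(t - t0, p, 1)
    if slope <= 0:
        return TriggerDecision("wait", None, float(slope))
    phase_now = intercept + slope * (now - t0)
    dphi = (config.target_phase - phase_now) % TWO_PI
    trigger_time = now + dphi / slope
    if trigger_time - now < config.latency:
        return TriggerDecision("skip_beat", trigger_time + TWO_PI / slope, float(slope))
    if trigger_time - now <= config.frame_interval + config.latency:
        return TriggerDecision("commit", float(trigger_time), float(slope))
    return TriggerDecision("wait", float(trigger_time), float(slope))


def _crossed_barrier(prev_idx: int, cur_idx: int, barrier: int, n: int) -> bool:
    """True when best_index passed the barrier cyclically between estimates."""
    if prev_idx == cur_idx:
        return False
    d_move = (cur_idx - prev_idx) % n
    if d_move > n // 2:  # backwards jitter, not a forward crossing
        return False
    d_barrier = (barrier - prev_idx) % n
    return 0 < d_barrier <= d_move


class _ListVideo:
    """Adapter giving random access + frame_rate over an in-memory frame list."""

    def __init__(self, frames, frame_rate=None):
        self.frames = list(frames)
        if frame_rate is None:
            ts = [f.timestamp for f in self.frames[:2]]
            frame_rate = 1.0 / (ts[1] - ts[0]) if len(ts) == 2 else 80.0
        self.frame_rate = frame_rate

    def frame(self, i: int) -> Frame:
        if i >= len(self.frames):
            raise GatingError("brightfield stream exhausted before the acquisition completed")
        return self.frames[i]

    def segment(self, start: int, n: int):
        return [self.frame(i) for i in range(start, start + n)]


def _as_video(video):
    if hasattr(video, "frame") and hasattr(video, "frame_rate"):
        return video
    return _ListVideo(video)


def run_timelapse(
    video,
    config: GatingConfig,
    n_planes: int,
    n_timepoints: int,
    truth=None,
    timepoint_interval: float | None = None,
    alignment_config=None,
    max_beats_per_plane: int = 20,
):
    """Phase-locked z-stack time-lapse: one trigger per plane per timepoint.

    ``video`` is any object with ``frame(i)`` and ``frame_rate`` (a
    SimulatedVideo, a TIFF-backed reader, or a plain frame list).  ``truth``
    may supply ``phase_at(t)`` (unwrapped radians) to log the realized true
    phase of every trigger.  Returns (records, manifest) where records is a
    list of TriggerRecord and manifest a JSON-ready summary including any
    phase-lock-loss events.
    """
    from .sequence_alignment import AlignmentConfig, AlignmentState, refresh_reference

    video = _as_video(video)
    if n_planes < 1 or n_timepoints < 1:
        raise ParameterError("n_planes and n_timepoints must be >= 1")
    fr = video.frame_rate
    acq_window = None
    cursor = 0

    def _try_acquire(at_cursor, seq_id, drift_origin):
        nonlocal acq_window
        for win_s in (1.0, 2.0, 4.0, 8.0) if acq_window is None else (acq_window,):
            n_win = int(round(win_s * fr))
            try:
                ref = acquire_reference(
                    video.segment(at_cursor, n_win), sequence_id=seq_id, drift_origin=drift_origin
                )
            except AcquisitionError:
                continue
            acq_window = max(3.5 * ref.period_frames / fr, 1.0)
            return ref, at_cursor + n_win
        return None

    def _acquire(at_cursor, seq_id, drift_origin, expected_period=None):
        """Acquire a reference; a period jumping > 25% from the previous one
        is treated as a misdetection and re-tried on shifted windows."""
        first = None
        cursor_try = at_cursor
        for _ in range(5):
            res = _try_acquire(cursor_try, seq_id, drift_origin)
            if res is not None:
                if first is None:
                    first = res
                period = res[0].period_frames
                if expected_period is None or abs(period - expected_period) <= 0.25 * expected_period:
                    return res
            cursor_try += int(round(0.5 * (acq_window or 1.0) * fr))
        if first is not None:
            events.append({"event": "period_discontinuity_accepted", "time": at_cursor / fr})
            return first
        raise AcquisitionError("could not acquire a reference sequence from the stream")

    records: list[TriggerRecord] = []
    events: list[dict] = []
    refs_meta: list[dict] = []
    ref, cursor = _acquire(cursor, 0, DriftOffset())
    refs_meta.append(
        {
            "sequence_id": ref.sequence_id,
            "acquired_at": ref.acquired_at,
            "period_frames": ref.period_frames,
            "barrier_frame": ref.barrier_frame,
        }
    )
    if alignment_config is None:
        alignment_config = AlignmentConfig()
    state = AlignmentState(ref, config.target_phase, alignment_config)
    target = config.target_phase
    drift = DriftOffset()
    cum_drift = (0, 0)
    history = PhaseHistory()
    next_seq_id = 1
    period_s = ref.period_frames / fr
    t_start = cursor / fr

    cfg = GatingConfig(**{**config.__dict__})

    def _refresh(reason: str):
        nonlocal ref, target, drift, cum_drift, cursor, next_seq_id, period_s
        cum_drift = (cum_drift[0] + drift.dx, cum_drift[1] + drift.dy)
        new_ref, new_cursor = _acquire(
            cursor, next_seq_id, DriftOffset(*cum_drift), expected_period=ref.period_frames
        )
        next_seq_id += 1
        try:
            target, _ = refresh_reference(state, new_ref, target)
        except Exception:  # alignment failure: keep the previous target, log it
            events.append({"event": "refresh_failed", "time": cursor / fr, "reason": reason})
        ref = new_ref
        refs_meta.append(
            {
                "sequence_id": ref.sequence_id,
                "acquired_at": ref.acquired_at,
                "period_frames": ref.period_frames,
                "barrier_frame": ref.barrier_frame,
            }
        )
        period_s = ref.period_frames / fr
        drift = DriftOffset()
        history.clear()
        cursor = new_cursor

    for tp in range(n_timepoints):
        for plane in range(n_planes):
            prev_idx = None
            last_unwrapped = None
            frames_this_plane = 0
            committed = False
            n_wait = n_skip = n_rate_blocked = 0
            while not committed:
                frame = video.frame(cursor)
                s = sad_score_vector(frame, ref, drift)
                cfg.target_phase = target
                est = match_phase(s, ref, frame, drift)
                drift = update_drift(frame, ref, est, drift)
                if last_unwrapped is None:
                    unwrapped = est.phase_radians
                else:
                    unwrapped = last_unwrapped + (wrap_to_pm_pi(est.phase_radians - (last_unwrapped % TWO_PI)))
                last_unwrapped = unwrapped
                if len(history) == 0 or frame.timestamp > history.timestamps[-1]:
                    history.append(frame.timestamp, unwrapped)
                if prev_idx is not None and _crossed_barrier(prev_idx, est.best_index, ref.barrier_frame, len(ref)):
                    history.barrier_crossings.append(frame.timestamp)
                prev_idx = est.best_index
                if len(history) < cfg.min_fit_points + 2:
                    decision = TriggerDecision("wait", None, 0.0)  # history too immature to trust a fit
                else:
                    decision = predict_trigger_time(history, ref, cfg, frame.timestamp)
                if decision.action == "commit":
                    # physiological sanity: the fitted rate must be within a
                    # factor of two of the reference's own beat rate
                    nominal = TWO_PI * fr / ref.period_frames
                    if not (0.5 * nominal <= decision.predicted_rate <= 2.0 * nominal):
                        decision = TriggerDecision("wait", None, decision.predicted_rate)
                        n_rate_blocked += 1
                if decision.action == "commit":
                    realized = truth.phase_at(decision.trigger_time) % TWO_PI if truth is not None else None
                    records.append(
                        TriggerRecord(
                            timepoint=tp,
                            plane=plane,
                            trigger_time=decision.trigger_time,
                            target_phase=target,
                            predicted_rate=decision.predicted_rate,
                            sequence_id=ref.sequence_id,
                            drift=(drift.dx, drift.dy),
                            realized_phase=realized,
                            frames_processed=frames_this_plane + 1,
                        )
                    )
                    cursor = int(np.ceil(decision.trigger_time * fr)) + 1
                    committed = True
                    break
                n_wait += decision.action == "wait"
                n_skip += decision.action == "skip_beat"
                cursor += 1
                frames_this_plane += 1
                if frames_this_plane > max_beats_per_plane * period_s * fr:
                    events.append(
                        {
                            "event": "phase_lock_lost",
                            "time": frame.timestamp,
                            "timepoint": tp,
                            "plane": plane,
                            "n_wait": n_wait,
                            "n_skip": n_skip,
                            "n_rate_blocked": n_rate_blocked,
                            "period_frames": ref.period_frames,
                            "barrier": ref.barrier_frame,
                        }
                    )
                    _refresh("phase_lock_lost")
                    prev_idx, last_unwrapped = None, None
                    frames_this_plane = 0
            do_refresh = (
                config.refresh_every == "every_n_planes"
                and config.refresh_n_planes > 0
                and (plane + 1) % config.refresh_n_planes == 0
                and not (plane + 1 == n_planes)
            )
            if do_refresh:
                _refresh("every_n_planes")
        if config.refresh_every == "per_stack" and tp < n_timepoints - 1:
            _refresh("per_stack")
        if timepoint_interval is not None and tp < n_timepoints - 1:
            cursor = max(cursor, int((t_start + (tp + 1) * timepoint_interval) * fr))
    manifest = {
        "n_planes": n_planes,
        "n_timepoints": n_timepoints,
        "n_triggers": len(records),
        "events": events,
        "references": refs_meta,
        "triggers": [
            {
                "timepoint": r.timepoint,
                "plane": r.plane,
                "trigger_time": r.trigger_time,
                "target_phase": r.target_phase,
                "predicted_rate": r.predicted_rate,
                "sequence_id": r.sequence_id,
                "drift": list(r.drift),
                "realized_phase": r.realized_phase,
            }
            for r in records
        ],
    }
    return records, manifest
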