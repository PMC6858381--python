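"""Downstream quantitative analyses.

* Heart-rate series from brightfield video, with sequential +-25% outlier
  rejection and re-determination (heart rate is the photo-injury readout).
* Photobleaching: volume-of-interest fluorescence quantification, single /
  double exponential decay fitting, and exp(n/tau) bleach compensation.
* Immune-cell track metrics (mean velocity, meandering index) and the
  "subsampled" / "decimated" virtual experiments that probe how time-lapse
  interval degrades track statistics.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, nnls

from .errors import InputFormatError, ParameterError, AcquisitionError
from .gating_controller import estimate_mean_period_frames

__all__ = [
    "HeartRateSeries",
    "BleachCurve",
    "BleachFit",
    "CellTrack",
    "LinkingParams",
    "heart_rate_series",
    "quantify_fluorescence",
    "fit_bleaching",
    "compensate_bleach",
    "track_metrics",
    "scaled_linking_params",
    "subsample_tracks",
    "decimate_tracks",
]


# ---------------------------------------------------------------- heart rate


@dataclass
class HeartRateSeries:
    times: np.ndarray  # window-centre times, s
    rates: np.ndarray  # beats per minute (NaN where no period found)
    rejected: np.ndarray  # True where the first determination was discarded


def _window_rate(frames, frame_rate: float, expected_rate: float | None = None) -> float:
    expected_period = 60.0 * frame_rate / expected_rate if expected_rate else None
    return 60.0 * frame_rate / estimate_mean_period_frames(frames, expected_period=expected_period)


def heart_rate_series(
    video, window: float, frame_rate: float | None = None, max_jump: float = 0.25, n_retries: int = 5
) -> HeartRateSeries:
    """Heart rate measured once per ``window`` seconds of brightfield video.

    Each window's period comes from the self-similarity period determination;
    rate = 60 * frame_rate / period_frames.  A rate differing by more than
    ``max_jump`` (+-25%) from the previously accepted value is flagged and
    re-determined on shifted sub-windows; if no re-determination falls within
    the band the measurement is recorded as missing (NaN) and the previous
    accepted value is carried for subsequent comparisons.
    """
    if hasattr(video, "frame") and hasattr(video, "frame_rate"):
        fr = video.frame_rate
        get = video.frame
        n_total = getattr(video, "n_frames", None)
    else:
        frames = list(video)
        fr = frame_rate if frame_rate is not None else 1.0 / (frames[1].timestamp - frames[0].timestamp)
        get = lambda i: frames[i]
        n_total = len(frames)
    if frame_rate is not None:
        fr = frame_rate
    win_frames = int(round(window * fr))
    if n_total is None:
        raise ParameterError("video must expose its frame count (n_frames) or be a finite sequence")
    n_windows = n_total // win_frames
    times, rates, rejected = [], [], []
    prev = None
    for k in range(n_windows):
        base = k * win_frames
        seg = [get(i) for i in range(base, base + win_frames)]
        def _redetermine():
            for attempt in range(1, n_retries + 1):
                shift = int(round(attempt * 0.15 * win_frames))
                lo = base + shift
                if lo + win_frames > n_total:
                    lo = max(0, base - shift)
                seg2 = [get(i) for i in range(lo, lo + win_frames)]
                try:
                    cand = _window_rate(seg2, fr, expected_rate=prev)
                except AcquisitionError:
                    continue
                if prev is None or abs(cand - prev) / prev <= max_jump:
                    return cand
            return np.nan

        flag = False
        try:
            rate = _window_rate(seg, fr, expected_rate=prev)
        except AcquisitionError:
            flag = True
            rate = _redetermine()
        if not flag and prev is not None and abs(rate - prev) / prev > max_jump:
            flag = True
            rate = _redetermine()
        times.append((base + 0.5 * win_frames) / fr)
        rates.append(rate)
        rejected.append(flag)
        if np.isfinite(rate):
            prev = rate
    return HeartRateSeries(np.array(times), np.array(rates), np.array(rejected, dtype=bool))


# -------------------------------------------------------------- photobleach


@dataclass
class BleachCurve:
    """Background-subtracted summed fluorescence per timepoint."""

    t: np.ndarray
    I: np.ndarray
    params: tuple | None = None
    model: str | None = None


@dataclass
class BleachFit:
    params: tuple  # (a, b, c, d, e); single-exponential fits report d = e = 0
    model: str
    residual_norm: float
    degenerate: bool = False
    near_equal_time_constants: bool = False

    def curve(self, t: np.ndarray) -> np.ndarray:
        a, b, c, d, e = self.params
        t = np.asarray(t, dtype=float)
        return a + b * np.exp(-c * t) + d * np.exp(-e * t)


def quantify_fluorescence(stacks: np.ndarray, background: float, voi=None) -> BleachCurve:
    """Summed background-subtracted intensity in a volume of interest.

    ``stacks`` has time on axis 0 (any number of spatial axes after it);
    ``voi`` is a tuple of slices into the spatial axes (None = everything).
    Negative background-subtracted voxels are clipped at zero before summing.
    """
    stacks = np.asarray(stacks, dtype=float)
    if background < 0:
        raise ParameterError("background must be >= 0")
    spatial_shape = stacks.shape[1:]
    if voi is not None:
        if len(voi) != len(spatial_shape):
            raise InputFormatError("voi must supply one slice per spatial axis")
        for sl, dim in zip(voi, spatial_shape):
            lo = 0 if sl.start is None else sl.start
            hi = dim if sl.stop is None else sl.stop
            if lo < 0 or hi > dim or lo >= hi:
                raise InputFormatError(f"voi slice {sl} outside axis of length {dim}")
        region = stacks[(slice(None),) + tuple(voi)]
    else:
        region = stacks
    vals = np.clip(region - background, 0.0, None)
    I = vals.reshape(vals.shape[0], -1).sum(axis=1)
    return BleachCurve(t=np.arange(stacks.shape[0], dtype=float), I=I)


def _double_exp(t, a, b, c, d, e):
    return a + b * np.exp(-c * t) + d * np.exp(-e * t)


def _single_exp(t, a, b, c):
    return a + b * np.exp(-c * t)


def _vp_initial_guess(t, y, model):
    """Variable-projection style initial guess: grid over decay rates, solve
    the amplitudes by non-negative least squares, keep the best."""
    span = max(t[-1] - t[0], 1.0)
    rates = np.geomspace(0.05 / span, 50.0 / span, 24)
    best = None
    if model == "single":
        for c in rates:
            X = np.column_stack([np.ones_like(t), np.exp(-c * t)])
            coef, rnorm = nnls(X, y)
            if best is None or rnorm < best[0]:
                best = (rnorm, (coef[0], coef[1], c))
        return best[1]
    for i, c in enumerate(rates):
        for e in rates[:i]:  # enforce c > e in the guess
            X = np.column_stack([np.ones_like(t), np.exp(-c * t), np.exp(-e * t)])
            coef, rnorm = nnls(X, y)
            if best is None or rnorm < best[0]:
                best = (rnorm, (coef[0], coef[1], c, coef[2], e))
    return best[1]


def fit_bleaching(curve: BleachCurve, model: str = "double") -> BleachFit:
    """Nonlinear least-squares fit of the decay law to a bleach curve.

    Model 'double': I(t) = a + b exp(-c t) + d exp(-e t); 'single' drops the
    second exponential (the constant term absorbs unbleached background such
    as blood autofluorescence).  Amplitudes are constrained non-negative and
    rates positive; the sum-ordering convention c > e is enforced.  Flags:
    ``degenerate`` when the fit collapses to a constant, and
    ``near_equal_time_constants`` when c and e agree within 10%.
    """
    t = np.asarray(curve.t, dtype=float)
    y = np.asarray(curve.I, dtype=float)
    if model not in ("single", "double"):
        raise ParameterError("model must be 'single' or 'double'")
    min_pts = 5 if model == "single" else 7
    if len(t) < min_pts:
        raise ParameterError(f"{model} fit needs at least {min_pts} points")
    yscale = max(float(np.max(np.abs(y))), 1e-12)
    if np.allclose(y, y[0], atol=1e-12 * yscale):
        params = (float(y[0]), 0.0, 0.0, 0.0, 0.0)
        fit = BleachFit(params=params, model=model, residual_norm=0.0, degenerate=True)
        curve.params, curve.model = params, model
        return fit
    p0 = _vp_initial_guess(t, y, model)
    tiny = 1e-12
    try:
        if model == "single":
            popt, _ = curve_fit(
                _single_exp, t, y, p0=p0, bounds=([0, 0, tiny], [np.inf] * 3), maxfev=20000
            )
            a, b, c = popt
            params = (float(a), float(b), float(c), 0.0, 0.0)
            resid = y - _single_exp(t, *popt)
        else:
            popt, _ = curve_fit(
                _double_exp, t, y, p0=p0, bounds=([0, 0, tiny, 0, tiny], [np.inf] * 5), maxfev=40000
            )
            a, b, c, d, e = popt
            if c < e:
                b, d = d, b
                c, e = e, c
            params = (float(a), float(b), float(c), float(d), float(e))
            resid = y - _double_exp(t, *params)
    except RuntimeError as err:
        raise RuntimeError(f"bleach fit did not converge (best initial guess {p0})") from err
    a, b, c, d, e = params
    degenerate = (b + d) < 1e-6 * max(a, yscale) or (model == "double" and c < 1e-10)
    near_eq = model == "double" and d > 0 and c > 0 and e > 0 and abs(c - e) < 0.1 * max(c, e)
    fit = BleachFit(
        params=params,
        model=model,
        residual_norm=float(np.linalg.norm(resid)),
        degenerate=bool(degenerate),
        near_equal_time_constants=bool(near_eq),
    )
    curve.params, curve.model = params, model
    return fit


def compensate_bleach(frames, tau: float):
    """Scale frame n by exp(n / tau) to undo gradual photobleaching.

    Accepts a (T, ...) array or a list of Frame objects; frame 0 is
    unchanged.  Returns the same container type.
    """
    if tau <= 0:
        raise ParameterError("tau must be > 0")
    if isinstance(frames, np.ndarray):
        gains = np.exp(np.arange(frames.shape[0]) / tau)
        return frames * gains.reshape((-1,) + (1,) * (frames.ndim - 1))
    from .phase_engine import Frame

    out = []
    for n, f in enumerate(frames):
        out.append(Frame(pixels=np.asarray(f.pixels) * np.exp(n / tau), timestamp=f.timestamp, index=f.index))
    return out


# ------------------------------------------------------------- cell tracks


@dataclass
class CellTrack:
    """Ordered (t, x, y, z) points of one tracked cell; times in seconds,
    coordinates in micrometres; ``frames`` are the source stack indices."""

    track_id: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    frames: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.frames is not None:
            self.frames = np.asarray(self.frames, dtype=int)
        if len(self.t) >= 2 and not np.all(np.diff(self.t) > 0):
            raise InputFormatError(f"track {self.track_id}: times must be strictly increasing")

    def __len__(self):
        return len(self.t)

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y, self.z])


def track_metrics(track: CellTrack):
    """(mean velocity um/min, meandering index) of a cell track.

    distance = sum of Euclidean step lengths, displacement = |last - first|,
    meandering index = displacement / distance in [0, 1] (defined as 1 for a
    degenerate zero-distance track), mean velocity = distance / elapsed time.
    """
    if len(track) < 2:
        raise ParameterError("track needs at least 2 points")
    pts = track.points
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    distance = float(steps.sum())
    displacement = float(np.linalg.norm(pts[-1] - pts[0]))
    elapsed_min = (track.t[-1] - track.t[0]) / 60.0
    if elapsed_min <= 0:
        raise ParameterError("track has zero elapsed time")
    meander = displacement / distance if distance > 0 else 1.0
    return distance / elapsed_min, meander


@dataclass(frozen=True)
class LinkingParams:
    """Nearest-neighbour linking parameters at the base time-lapse interval.

    Defaults follow a 3-minute interval with a 10 um/min velocity bound:
    linking distance 30 um, gap-closing distance 60 um over at most 2 missed
    frames.
    """

    max_linking_distance: float = 30.0
    max_gap_distance: float = 60.0
    max_gap_frames: int = 2
    frame_interval_min: float = 3.0


def scaled_linking_params(k: int, base: LinkingParams = LinkingParams()) -> LinkingParams:
    """Linking parameters for a k-fold longer interval: distances scale by k
    so the same maximum cell velocity is captured."""
    if k < 1:
        raise ParameterError("interval factor k must be >= 1")
    return LinkingParams(
        max_linking_distance=k * base.max_linking_distance,
        max_gap_distance=k * base.max_gap_distance,
        max_gap_frames=base.max_gap_frames,
        frame_interval_min=k * base.frame_interval_min,
    )


def _link_detections(det: pd.DataFrame, params: LinkingParams) -> list:
    """Greedy nearest-neighbour linker over per-frame detections.

    ``det`` columns: frame, t, x, y, z.  Frames here are consecutive indices
    of the (possibly subsampled) dataset.  Direct links span one frame within
    ``max_linking_distance``; gap closing spans up to ``max_gap_frames``
    missed frames within ``max_gap_distance``.
    """
    tracks: list[dict] = []
    open_tracks: list[dict] = []
    for f in sorted(det["frame"].unique()):
        rows = det[det["frame"] == f]
        pts = rows[["x", "y", "z"]].to_numpy(dtype=float)
        ts = rows["t"].to_numpy(dtype=float)
        candidates = []
        for ti, tr in enumerate(open_tracks):
            gap = f - tr["frames"][-1]
            if gap < 1 or gap > params.max_gap_frames + 1:
                continue
            limit = params.max_linking_distance if gap == 1 else params.max_gap_distance
            d = np.linalg.norm(pts - tr["pts"][-1], axis=1)
            for di in np.flatnonzero(d <= limit):
                candidates.append((d[di], ti, int(di)))
        used_tracks, used_dets = set(), set()
        for dist, ti, di in sorted(candidates):
            if ti in used_tracks or di in used_dets:
                continue
            tr = open_tracks[ti]
            tr["pts"].append(pts[di])
            tr["ts"].append(ts[di])
            tr["frames"].append(int(f))
            used_tracks.add(ti)
            used_dets.add(di)
        for di in range(len(pts)):
            if di not in used_dets:
                tr = {"pts": [pts[di]], "ts": [ts[di]], "frames": [int(f)]}
                tracks.append(tr)
                open_tracks.append(tr)
        open_tracks = [tr for tr in open_tracks if f - tr["frames"][-1] <= params.max_gap_frames]
    out = []
    for tid, tr in enumerate(tracks):
        p = np.array(tr["pts"])
        out.append(
            CellTrack(
                track_id=tid,
                t=np.array(tr["ts"]),
                x=p[:, 0],
                y=p[:, 1],
                z=p[:, 2],
                frames=np.array(tr["frames"]),
            )
        )
    return out


def subsample_tracks(points: pd.DataFrame, k: int, base: LinkingParams = LinkingParams()) -> list:
    """Virtual experiment at a k-fold longer interval: keep every k-th stack
    and re-link with k-scaled distances.

    ``points`` columns: frame (stack index), t (s), x, y, z (um).  Detections
    are inputs; only the linking is performed here.
    """
    required = {"frame", "t", "x", "y", "z"}
    if not required.issubset(points.columns):
        raise InputFormatError(f"points table needs columns {sorted(required)}")
    params = scaled_linking_params(k, base)  # validates k
    kept = points[points["frame"] % k == 0].copy()
    kept["frame"] = kept["frame"] // k
    return _link_detections(kept, params)


def decimate_tracks(tracks, k: int):
    """Keep only points on the k-grid of stack indices, PRESERVING linkage.

    This is the ground-truth-like upper bound for longer intervals: the
    original (short-interval) linking is retained, only intermediate points
    are removed.  Tracks left with fewer than 2 points are dropped.
    """
    if k < 1:
        raise ParameterError("interval factor k must be >= 1")
    out = []
    for tr in tracks:
        if tr.frames is None:
            raise InputFormatError("decimation requires tracks with stack indices")
        keep = tr.frames % k == 0
        if keep.sum() < 2:
            continue
        out.append(
            CellTrack(
                track_id=tr.track_id,
                t=tr.t[keep],
                x=tr.x[keep],
                y=tr.y[keep],
                z=tr.z[keep],
                frames=tr.frames[keep] // k,
            )
        )
    return out
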