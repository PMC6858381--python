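"""Synthetic beating-heart video with per-frame ground truth.

The simulator renders a parametric two-chamber scene (deforming elliptical
annuli for ventricle and atrium over a static background structure) whose
shape is a deterministic function of the true cardiac phase.  It reproduces
the statistical structure the gating algorithms rely on:

* quasi-periodicity — beat periods drawn with a configurable coefficient of
  variation (CV);
* a low-motion refractory interval between beats whose duration carries
  *extra* per-beat variability, redistributed within the beat so that the
  total period CV stays at ``period_jitter_cv``;
* slow morphogenesis — chamber size and separation grow by ``morph_rate``
  per simulated hour;
* uniform in-plane drift, transient non-periodic blood speckles, and
  additive Gaussian intensity noise.

Phase convention: each beat starts at the end of the refractory interval
(phase 0), contracts through the active interval [0, 2*pi*(1-f_r)) and is
quiescent over the remaining refractory band, advancing by exactly 2*pi per
beat.  The two chambers contract with differently skewed waveforms so that
the (ventricle, atrium) shape pair is unambiguous across the cycle.

All randomness is derived from the single spec seed via independent
sub-streams (beat jitter / noise / speckles); noise and speckles are keyed
per frame index so frames can be rendered lazily in any order with
bit-identical results.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._util import TWO_PI
from .errors import ParameterError
from .phase_engine import Frame

__all__ = [
    "SyntheticHeartSpec",
    "GroundTruth",
    "SimulatedVideo",
    "simulate_brightfield",
    "simulate_fluorescence_decay",
    "fluorescence_heart_mask",
]


@dataclass(frozen=True)
class SyntheticHeartSpec:
    """Full parameterization of the simulated beating heart.

    Units: ``frame_rate`` frames/s, ``mean_period`` s/beat, ``drift_velocity``
    (px/min, px/min), ``morph_rate`` fractional growth per hour,
    ``blood_speckle_rate`` expected speckles per frame, ``rate_ramp_bpm_per_min``
    linear heart-rate ramp (0 = constant rate).
    """

    frame_rate: float = 80.0
    image_shape: tuple = (64, 64)
    mean_period: float = 0.4
    period_jitter_cv: float = 0.05
    refractory_fraction: float = 0.25
    refractory_jitter_cv: float = 0.15
    morph_rate: float = 0.1
    drift_velocity: tuple = (0.1, 0.05)
    noise_sd: float = 15.0
    blood_speckle_rate: float = 1.5
    rate_ramp_bpm_per_min: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.mean_period <= 0:
            raise ParameterError("mean_period must be > 0")
        if not (0 < self.refractory_fraction < 1):
            raise ParameterError("refractory_fraction must lie in (0, 1)")
        if self.frame_rate <= 0:
            raise ParameterError("frame_rate must be > 0")
        for name in ("period_jitter_cv", "refractory_jitter_cv", "noise_sd", "blood_speckle_rate"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if len(self.image_shape) != 2 or min(self.image_shape) < 16:
            raise ParameterError("image_shape must be (rows, cols) with both >= 16")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticHeartSpec":
        data = json.loads(text)
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown spec fields: {sorted(unknown)}")
        if "image_shape" in data:
            data["image_shape"] = tuple(data["image_shape"])
        if "drift_velocity" in data:
            data["drift_velocity"] = tuple(data["drift_velocity"])
        return cls(**data)


@dataclass
class GroundTruth:
    """Per-frame truth for a rendered sequence.

    ``phase`` is wrapped to [0, 2pi); ``unwrapped_phase`` advances by exactly
    2*pi per beat; ``drift`` is the true (dx, dy) translation in pixels;
    ``refractory_intervals`` are per-beat (start, end) frame indices
    (half-open) and ``beat_boundaries`` the beat start times in seconds.
    """

    phase: np.ndarray
    unwrapped_phase: np.ndarray
    drift: np.ndarray
    refractory_intervals: list
    beat_boundaries: np.ndarray
    frame_rate: float
    _schedule: "_BeatSchedule" = field(default=None, repr=False)

    def phase_at(self, t: float) -> float:
        """Unwrapped true phase at an arbitrary time (analytic, not interpolated)."""
        if self._schedule is not None:
            return self._schedule.unwrapped_phase_at(t)
        ts = np.arange(len(self.unwrapped_phase)) / self.frame_rate
        return float(np.interp(t, ts, self.unwrapped_phase))

    def periods(self) -> np.ndarray:
        return np.diff(self.beat_boundaries)


class _BeatSchedule:
    """Lazily extended sequence of beats with jittered periods.

    Beat k spans [b_k, b_{k+1}); the active interval comes first (phase
    [0, phi_r)), the refractory interval last (phase [phi_r, 2pi)), with
    phi_r = 2pi * (1 - refractory_fraction).
    """

    def __init__(self, spec: SyntheticHeartSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.boundaries = [0.0]
        self.active = []  # A_k seconds
        self.refr = []  # D_k seconds
        self.phi_r = TWO_PI * (1.0 - spec.refractory_fraction)

    def _mean_period_at(self, t: float) -> float:
        base_bpm = 60.0 / self.spec.mean_period
        bpm = base_bpm + self.spec.rate_ramp_bpm_per_min * (t / 60.0)
        return 60.0 / max(bpm, 1.0)

    def _extend_one(self):
        t0 = self.boundaries[-1]
        mp = self._mean_period_at(t0)
        eps = np.clip(self.rng.normal(0.0, self.spec.period_jitter_cv), -0.8, 0.8)
        period = mp * (1.0 + eps)
        eta = np.clip(self.rng.normal(0.0, self.spec.refractory_jitter_cv), -0.8, 0.8)
        refr = period * self.spec.refractory_fraction * (1.0 + eta)
        refr = min(refr, 0.9 * period)
        self.refr.append(refr)
        self.active.append(period - refr)
        self.boundaries.append(t0 + period)

    def ensure(self, t: float):
        while self.boundaries[-1] <= t:
            self._extend_one()

    def beat_index_at(self, t: float) -> int:
        self.ensure(t)
        return int(np.searchsorted(self.boundaries, t, side="right") - 1)

    def phase_at(self, t: float) -> float:
        """Alias for unwrapped_phase_at (truth-provider protocol)."""
        return self.unwrapped_phase_at(t)

    def unwrapped_phase_at(self, t: float) -> float:
        if t < 0:
            raise ParameterError("time must be >= 0")
        k = self.beat_index_at(t)
        tau = t - self.boundaries[k]
        a, d = self.active[k], self.refr[k]
        if tau < a:
            phi = self.phi_r * tau / a
        else:
            phi = self.phi_r + (TWO_PI - self.phi_r) * (tau - a) / d
        return TWO_PI * k + min(phi, TWO_PI)

    def wrapped_phase_at(self, t: float) -> float:
        return self.unwrapped_phase_at(t) % TWO_PI


def _waveform(phi: float, phi_r: float, skew: float, relax: float = 0.06) -> float:
    """Contraction waveform over one cycle.

    Active interval [0, phi_r): a skewed raised-cosine hump (fast onset for
    skew < 1) riding on a slow linear recovery from the diastolic filling
    level -relax back to 0.  Refractory band [phi_r, 2pi): slow monotone
    relaxation 0 -> -relax (gentle chamber filling), so motion there is tiny
    compared to the contraction but frames remain distinguishable — as in
    real diastole.  Continuous and periodic across the beat boundary.
    """
    if phi >= phi_r:
        s = (phi - phi_r) / (TWO_PI - phi_r)
        return -relax * s
    u = phi / phi_r
    h = 0.5 * (1.0 - np.cos(TWO_PI * u**skew))
    return h - relax * (1.0 - u)


class SimulatedVideo:
    """Lazy frame source backed by the parametric scene renderer.

    Frames are addressed by index on the stream timebase (frame i at
    t = i / frame_rate) and rendered on demand, so day-long experiments can
    be simulated without materialising every brightfield frame.
    """

    def __init__(self, spec: SyntheticHeartSpec):
        self.spec = spec
        ss = np.random.SeedSequence(spec.seed)
        beat_ss, self._noise_root, self._speckle_root = ss.spawn(3)
        self.schedule = _BeatSchedule(spec, np.random.default_rng(beat_ss))
        h, w = spec.image_shape
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
        self._yy, self._xx = yy, xx
        self._cy0, self._cx0 = h / 2.0, w / 2.0
        # chamber layout in sample coordinates (fractions of the image)
        self._chambers = [
            # (cy, cx, ry, rx, amplitude, contraction depth, waveform skew)
            (0.40 * h, 0.38 * w, 0.19 * h, 0.17 * w, 1500.0, 0.18, 0.60),  # ventricle
            (0.63 * h, 0.62 * w, 0.14 * h, 0.13 * w, 1200.0, 0.22, 0.85),  # atrium
        ]

    @property
    def frame_rate(self) -> float:
        return self.spec.frame_rate

    @property
    def truth(self) -> _BeatSchedule:
        return self.schedule

    def true_drift_at(self, t: float):
        vx, vy = self.spec.drift_velocity
        return (vx * t / 60.0, vy * t / 60.0)

    def render(self, t: float) -> np.ndarray:
        """Noise-free scene at time t (float32, arbitrary intensity units)."""
        spec = self.spec
        phi = self.schedule.wrapped_phase_at(t)
        m = 1.0 + spec.morph_rate * t / 3600.0
        dx, dy = self.true_drift_at(t)
        xs = self._xx - dx
        ys = self._yy - dy
        img = np.full(spec.image_shape, 200.0, dtype=np.float32)
        # static anchor structures (drift with the sample, do not morph)
        img += 60.0 * (xs / spec.image_shape[1])
        h, w = spec.image_shape
        blob = 350.0 * np.exp(-(((ys - 0.15 * h) ** 2) + ((xs - 0.80 * w) ** 2)) / (2.0 * (0.06 * min(h, w)) ** 2))
        img += blob
        for cy, cx, ry, rx, amp, depth, skew in self._chambers:
            wv = _waveform(phi, self.schedule.phi_r, skew)
            # morphogenesis scales radii and pushes chambers apart
            gy = self._cy0 + (cy - self._cy0) * m
            gx = self._cx0 + (cx - self._cx0) * m
            r_y = ry * m * (1.0 - depth * wv)
            r_x = rx * m * (1.0 - depth * wv)
            u2 = ((ys - gy) / r_y) ** 2 + ((xs - gx) / r_x) ** 2
            r = np.sqrt(u2)
            img += amp * np.exp(-((r - 1.0) ** 2) / (2.0 * 0.08**2))
            img += 0.30 * amp * np.exp(-u2 / 0.45)
        # travelling contraction wave: a bright spot orbiting the heart once
        # per cycle.  Without it the scene would be ambiguous between the
        # contraction and relaxation strokes (both chambers pass through the
        # same radii twice per beat); the wave position makes every phase
        # image-distinct, as the peristaltic activation sequence does in a
        # real heart.  It covers 90% of its orbit during the active interval
        # and crawls through the remaining 10% during the refractory band,
        # so the quiescent interval keeps its low-motion character.
        phi_r = self.schedule.phi_r
        if phi < phi_r:
            theta = 0.9 * TWO_PI * (phi / phi_r)
        else:
            theta = 0.9 * TWO_PI + 0.1 * TWO_PI * (phi - phi_r) / (TWO_PI - phi_r)
        r_orb = 0.33 * min(h, w) * m
        by = self._cy0 + r_orb * np.sin(theta)
        bx = self._cx0 + r_orb * np.cos(theta)
        img += 300.0 * np.exp(-(((ys - by) ** 2) + ((xs - bx) ** 2)) / (2.0 * 3.0**2))
        return img

    def frame(self, i: int) -> Frame:
        if i < 0:
            raise ParameterError("frame index must be >= 0")
        t = i / self.spec.frame_rate
        img = self.render(t)
        spec = self.spec
        if spec.blood_speckle_rate > 0:
            srng = np.random.default_rng([self._speckle_root.entropy, 1, i])
            n = srng.poisson(spec.blood_speckle_rate)
            h, w = spec.image_shape
            for _ in range(n):
                sy, sx = srng.uniform(0, h), srng.uniform(0, w)
                amp = srng.uniform(100.0, 400.0)
                img += amp * np.exp(-(((self._yy - sy) ** 2) + ((self._xx - sx) ** 2)) / 2.0)
        if spec.noise_sd > 0:
            nrng = np.random.default_rng([self._noise_root.entropy, 2, i])
            img = img + nrng.normal(0.0, spec.noise_sd, size=img.shape)
        np.clip(img, 0.0, None, out=img)
        return Frame(pixels=img.astype(np.float32), timestamp=t, index=i)

    def segment(self, start: int, n: int) -> list:
        return [self.frame(i) for i in range(start, start + n)]


def simulate_brightfield(spec: SyntheticHeartSpec, duration: float):
    """Render ``duration`` seconds of brightfield video plus ground truth."""
    if duration < 2.0 * spec.mean_period:
        raise ParameterError("duration must cover at least two heartbeats")
    video = SimulatedVideo(spec)
    n = int(round(duration * spec.frame_rate))
    frames = video.segment(0, n)
    sched = video.schedule
    sched.ensure(duration + spec.mean_period)
    times = np.arange(n) / spec.frame_rate
    unwrapped = np.array([sched.unwrapped_phase_at(t) for t in times])
    drift = np.array([video.true_drift_at(t) for t in times])
    n_beats = int(np.searchsorted(sched.boundaries, times[-1], side="right"))
    boundaries = np.array(sched.boundaries[: n_beats + 1])
    refractory = []
    for k in range(n_beats):
        r0 = sched.boundaries[k] + sched.active[k]
        r1 = sched.boundaries[k + 1]
        i0 = int(np.ceil(r0 * spec.frame_rate))
        i1 = int(np.ceil(r1 * spec.frame_rate))
        refractory.append((min(i0, n), min(i1, n)))
    gt = GroundTruth(
        phase=unwrapped % TWO_PI,
        unwrapped_phase=unwrapped,
        drift=drift,
        refractory_intervals=refractory,
        beat_boundaries=boundaries,
        frame_rate=spec.frame_rate,
        _schedule=sched,
    )
    return frames, gt


def fluorescence_heart_mask(spec: SyntheticHeartSpec) -> np.ndarray:
    """Boolean disk mask covering the simulated heart in fluorescence frames."""
    h, w = spec.image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = 0.30 * min(h, w)
    return ((yy - h / 2.0) ** 2 + (xx - w / 2.0) ** 2) <= r**2


def simulate_fluorescence_decay(spec: SyntheticHeartSpec, n_frames: int, model_params) -> list:
    """Fluorescence frames whose in-mask mean follows a double-exponential decay.

    Frame t (t = 0..n_frames-1) has mean intensity inside the heart mask of
    a + b*exp(-c*t) + d*exp(-e*t), plus additive noise of SD ``spec.noise_sd``.
    """
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    a, b, c, d, e = model_params
    if a < 0 or b < 0 or d < 0:
        raise ParameterError("amplitudes a, b, d must be non-negative")
    mask = fluorescence_heart_mask(spec)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(4)[3])
    frames = []
    for t in range(n_frames):
        level = a + b * np.exp(-c * t) + d * np.exp(-e * t)
        img = np.zeros(spec.image_shape, dtype=np.float32)
        img[mask] = level
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape).astype(np.float32)
            np.clip(img, 0.0, None, out=img)
        frames.append(Frame(pixels=img, timestamp=t / spec.frame_rate, index=t))
    return frames
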