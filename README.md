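# heartsync

Adaptive prospective optical gating for day-long, phase-locked 3D time-lapse
imaging of the beating embryonic heart.

Fluorescence imaging of a beating zebrafish heart must "freeze" cardiac
motion without drugging the heart or flooding it with excitation light.
Prospective optical gating solves this by watching a harmless brightfield
video stream, assigning each frame a cardiac phase, and firing the
fluorescence camera only at the instant the heart returns to a chosen target
phase — one image per z-plane per timepoint, nothing wasted.  Over
developmental timescales the heart changes shape, so a reference heartbeat
recorded at the start of an experiment stops matching after roughly an hour
and phase-lock is lost.  This package implements the full algorithmic stack
that keeps the lock for day-long experiments, together with a synthetic
beating-heart simulator that provides ground truth for every claim, and the
downstream analyses (heart rate, photobleaching, immune-cell track metrics).
It is aimed at microscopists and image-analysis developers who want to
study, extend or re-validate real-time cardiac gating logic without a
microscope.

## The method

**Phase assignment.** Each brightfield frame `I_t` is compared against a
reference sequence `R_phi` spanning exactly one heartbeat (padded with two
extra frames at each end) with a sum of absolute differences,

    s_phi = sum_xy | I_t(x,y) - R_phi(x+dx, y+dy) |,

where `(dx, dy)` is the tracked in-plane sample drift.  The arg-min over
non-padding frames gives the integer phase, refined to sub-frame precision
by fitting a V function to the three scores around the minimum:

    phi' = (s_{phi-1} - s_{phi+1}) / (2 (max(s_{phi-1}, s_{phi+1}) - s_phi)).

**Forward prediction.** A linear fit of unwrapped phase versus time is
extrapolated to the next crossing of the target phase.  The fit uses only
frames received since the *barrier frame* — the reference index marking the
end of the variable-duration inter-beat refractory period — was last passed
(minimum three points), because the refractory interval's length varies from
beat to beat and fitting across it ruins the extrapolation.  A trigger is
committed only when the predicted time is within one frame interval plus the
known processing latency (12 ms by default).

**Day-long phase-lock.** After each z-stack the reference sequence is
refreshed.  Each refreshed heartbeat is resampled to a fixed number of
frames and aligned to up to three recent reference heartbeats by cyclic
cross-correlation along the phase axis (computed in Fourier space).  Because
each pairwise shift is only known modulo 2*pi, the over-determined system
`A x = r` is solved by a multi-pass algorithm: solve with only adjacent
pairs, re-wrap every measurement onto the solution by adding multiples of
2*pi, and repeat with increasing pairing distance.  The target phase is then
mapped into the new reference, so the locked phase never drifts even as the
heart grows and remodels.

## Worked example

```python
import numpy as np
from heartsync.synthetic_heart import SyntheticHeartSpec, SimulatedVideo
from heartsync.gating_controller import GatingConfig, run_timelapse
from heartsync._util import circular_sd

spec = SyntheticHeartSpec(seed=7)          # 150 bpm heart, jitter, growth, drift
video = SimulatedVideo(spec)               # lazy frame source, 80 fps
cfg = GatingConfig(target_phase=1.0)       # lock 1 rad after the refractory period

records, manifest = run_timelapse(
    video, cfg, n_planes=4, n_timepoints=48,
    truth=video.truth, timepoint_interval=150.0,   # a stack every 150 s for 2 h
)
phases = np.array([r.realized_phase for r in records])
print(len(records), round(circular_sd(phases), 4))
```

This prints `192 0.0372`: the run produced exactly 4 x 48 = 192 fluorescence
triggers (one per plane per timepoint — the no-redundant-excitation
invariant) and the true cardiac phase realized at those triggers has a
circular standard deviation of about 0.03 rad, i.e. the lock held to a small
fraction of a brightfield frame across two simulated hours of heart growth
and drift.  Running the same experiment with `refresh_every="never"` makes
the realized phase drift by more than 3 rad — the failure mode of
non-adaptive gating that the reference-refresh machinery exists to prevent.

The same functionality is exposed on the command line:

```
heartsync simulate --spec spec.json --duration 60 --out video.tif --truth truth.csv
heartsync gate --video video.tif --planes 4 --timepoints 10 --truth truth.csv --out manifest.json
heartsync heartrate --video video.tif --window 60
heartsync bleach --stacks stacks.tif --model double
heartsync tracks --points detections.csv --subsample 2
```

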