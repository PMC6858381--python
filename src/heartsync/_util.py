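"""Small numeric helpers: angle wrapping, circular statistics, V-fitting."""
from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_to_2pi(phi):
    """Wrap angle(s) into [0, 2*pi)."""
    return np.mod(phi, TWO_PI)


def wrap_to_pm_pi(phi):
    """Wrap angle(s) into (-pi, pi]."""
    w = np.mod(phi + np.pi, TWO_PI) - np.pi
    # np.mod maps the boundary to -pi; the convention here is (-pi, pi]
    if np.isscalar(w) or w.ndim == 0:
        return np.pi if w == -np.pi else float(w)
    w = np.asarray(w)
    w[w == -np.pi] = np.pi
    return w


def circular_mean(phi):
    phi = np.asarray(phi, dtype=float)
    return float(np.arctan2(np.sin(phi).mean(), np.cos(phi).mean()))


def circular_sd(phi):
    """Circular standard deviation sqrt(-2 ln Rbar) in radians."""
    phi = np.asarray(phi, dtype=float)
    rbar = np.hypot(np.sin(phi).mean(), np.cos(phi).mean())
    rbar = min(max(rbar, 1e-12), 1.0)
    return float(np.sqrt(-2.0 * np.log(rbar)))


def vfit_min_offset(s_left: float, s_mid: float, s_right: float):
    """Sub-sample offset of a V-shaped minimum from three samples.

    Fits s = |phi - phi'| * slope + s_min to the triple (s_left, s_mid,
    s_right) assumed to bracket the minimum at the centre sample, giving

        offset = (s_left - s_right) / (2 * (max(s_left, s_right) - s_mid))

    Returns (offset, degenerate).  A flat triple (zero denominator) is
    degenerate and reported as offset 0; a centre sample that is not the
    smallest (possible when an on-demand padding score undercuts it) is
    clipped to the +-0.5 boundary and also flagged.
    """
    denom = 2.0 * (max(s_left, s_right) - s_mid)
    if denom == 0.0:
        return 0.0, True
    off = (s_left - s_right) / denom
    if denom < 0.0 or abs(off) > 0.5:
        return float(np.clip(off, -0.5, 0.5)), True
    return float(off), False
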