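"""Headline dynamical features of a trajectory: peak, time-to-basal,
response class, dose similarity.

The nuclear IL-1 response is a pulse (acute phase then return to basal); the
cytosolic/membrane response is a step-like transient; unstimulated species
are flat.  "Reaching the basal level" is operationalized as first entry into
a band of +/- rel_tol * basal around the basal value (rel_tol defaults to
0.01); that convention is configurable and reported with the feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError
from .simulate import Trajectory

__all__ = [
    "ResponseFeatures",
    "peak",
    "time_to_basal",
    "classify_response",
    "dose_similarity",
    "full_width_half_max",
    "extract_features",
]

PULSE, STEP, FLAT = "pulse", "step", "flat"


@dataclass
class ResponseFeatures:
    """Feature summary for one observable of one scenario."""

    species: str
    peak_time: float  # s
    peak_value: float  # nM
    basal_value: float  # nM
    time_to_basal: float  # s (nan when no peak)
    terminal_value: float  # nM
    response_class: str
    rel_tol: float = 0.01  # basal-band convention used for time_to_basal
    flags: tuple[str, ...] = field(default_factory=tuple)


def _series(trajectory: Trajectory, species: str) -> np.ndarray:
    x = trajectory[species]
    if trajectory.times.size < 3:
        raise InvalidArgumentError("need at least 3 time points")
    return x


def peak(trajectory: Trajectory, species: str):
    """Location and height of the maximum, sub-grid-refined.

    The discrete maximum is refined by a quadratic through the three
    bracketing points, so peak_time is grid-independent to sub-step
    accuracy.  Ties break to the earliest time.  A trajectory with no
    interior maximum returns its terminal point flagged
    ``no_interior_peak``.

    Returns ``(peak_time, peak_value, flags)``.
    """
    t = trajectory.times
    x = _series(trajectory, species)
    i = int(np.argmax(x))  # argmax returns the first (earliest) maximum
    interior = 0 < i < len(x) - 1 and (x[i] > x[0] or x[i] > x[-1])
    if not interior or np.allclose(x, x[0], rtol=0.0, atol=1e-15):
        return float(t[-1]), float(x[-1]), ("no_interior_peak",)
    t0, t1, t2 = t[i - 1], t[i], t[i + 1]
    y0, y1, y2 = x[i - 1], x[i], x[i + 1]
    # vertex of the interpolating parabola (guard a degenerate denominator)
    denom = (t1 - t0) * (y1 - y2) - (t1 - t2) * (y1 - y0)
    if denom == 0.0:
        return float(t1), float(y1), ()
    tp = t1 - 0.5 * ((t1 - t0) ** 2 * (y1 - y2) - (t1 - t2) ** 2 * (y1 - y0)) / denom
    tp = float(np.clip(tp, t0, t2))
    # parabola height at the vertex (Lagrange form)
    yp = (
        y0 * (tp - t1) * (tp - t2) / ((t0 - t1) * (t0 - t2))
        + y1 * (tp - t0) * (tp - t2) / ((t1 - t0) * (t1 - t2))
        + y2 * (tp - t0) * (tp - t1) / ((t2 - t0) * (t2 - t1))
    )
    return tp, float(max(yp, y1)), ()


def time_to_basal(trajectory: Trajectory, species: str, basal: float,
                  rel_tol: float = 0.01):
    """First time after the peak at which the observable is within the basal
    band |x - basal| <= rel_tol * max(basal, peak_value * 1e-3).

    Located by linear interpolation between bracketing grid points.  Returns
    ``(time, flags)``; a trajectory that never re-enters the band returns
    the horizon flagged ``censored``.
    """
    if basal < 0:
        raise InvalidArgumentError("basal must be >= 0")
    t = trajectory.times
    x = _series(trajectory, species)
    pk_t, pk_v, pk_flags = peak(trajectory, species)
    if "no_interior_peak" in pk_flags:
        return float(t[-1]), ("no_peak",)
    band = rel_tol * max(basal, pk_v * 1e-3)
    post = t > pk_t
    idx = np.nonzero(post)[0]
    d = np.abs(x - basal) - band
    if d[idx[0]] <= 0.0:
        return float(t[idx[0]]), ("degenerate",)
    for j in idx[1:]:
        if d[j] <= 0.0:
            # linear interpolation of the band crossing
            frac = d[j - 1] / (d[j - 1] - d[j])
            return float(t[j - 1] + frac * (t[j] - t[j - 1])), ()
    return float(t[-1]), ("censored",)


def _rise_and_plateau(t, x, pk_v):
    """Time to first reach 90% of peak, and total time spent at >= 90%."""
    thr = 0.9 * pk_v
    above = x >= thr
    if not above.any():
        return float(t[-1]), 0.0
    first = int(np.argmax(above))
    if first == 0:
        rise = float(t[0])
    else:
        frac = (thr - x[first - 1]) / (x[first] - x[first - 1])
        rise = float(t[first - 1] + frac * (t[first] - t[first - 1]))
    dt = np.diff(t)
    plateau = float(np.sum(dt[above[:-1] & above[1:]]))
    return max(rise, float(t[1])), plateau


def classify_response(trajectory: Trajectory, species: str, basal: float):
    """Classify an observable's time course as pulse / step / flat.

    pulse: peak exceeds basal and terminal by > 10% and the terminal value
    returns to basal.  step: the observable rises and holds >= 90% of its
    peak for at least 5x the rise time before any decline.  flat: neither
    (including everything whose excursion above basal is negligible).

    Returns ``(response_class, flags)``; a trajectory matching no pattern
    cleanly is classified flat with a ``low_confidence`` flag.
    """
    t = trajectory.times
    x = _series(trajectory, species)
    pk_t, pk_v, _ = peak(trajectory, species)
    terminal = float(x[-1])
    amplitude = pk_v - basal
    if amplitude <= max(0.1 * basal, 1e-6):
        return FLAT, ()
    rise, plateau = _rise_and_plateau(t, x, pk_v)
    if plateau >= 5.0 * rise:
        return STEP, ()
    terminal_near_basal = abs(terminal - basal) <= max(0.1 * basal, 0.02 * pk_v)
    if pk_v > 1.1 * basal and pk_v > 1.1 * terminal and terminal_near_basal:
        return PULSE, ()
    return FLAT, ("low_confidence",)


def dose_similarity(traj_a: Trajectory, traj_b: Trajectory, species: str) -> float:
    """1 - ||a - b||_L2 / ||a||_L2 over the common time grid, clipped to [0, 1].

    The first trajectory is the reference for normalization (the measure is
    symmetric up to this choice); ``b`` is resampled onto ``a``'s grid by
    linear interpolation when the grids differ.
    """
    a = traj_a[species]
    ta = traj_a.times
    if traj_b.times.shape == ta.shape and np.array_equal(traj_b.times, ta):
        b = traj_b[species]
    else:
        b = np.interp(ta, traj_b.times, traj_b[species])
    ref = np.sqrt(np.trapezoid(a * a, ta))
    if ref == 0.0:
        raise InvalidArgumentError("all-zero reference trajectory")
    dist = np.sqrt(np.trapezoid((a - b) ** 2, ta))
    return float(np.clip(1.0 - dist / ref, 0.0, 1.0))


def full_width_half_max(trajectory: Trajectory, species: str, basal: float) -> float:
    """Width of the pulse at half of its height above basal (s).

    nan when there is no interior peak; the horizon bounds the width when
    the trajectory has not yet fallen back below half height.
    """
    t = trajectory.times
    x = _series(trajectory, species)
    pk_t, pk_v, flags = peak(trajectory, species)
    if "no_interior_peak" in flags:
        return float("nan")
    half = basal + 0.5 * (pk_v - basal)
    above = x >= half
    i_pk = int(np.searchsorted(t, pk_t))
    i_pk = min(max(i_pk, 0), len(t) - 1)
    left = i_pk
    while left > 0 and above[left - 1]:
        left -= 1
    right = i_pk
    while right < len(t) - 1 and above[min(right + 1, len(t) - 1)]:
        right += 1
    # interpolate the two half-height crossings
    if left == 0:
        t_left = float(t[0])
    else:
        frac = (half - x[left - 1]) / (x[left] - x[left - 1])
        t_left = float(t[left - 1] + frac * (t[left] - t[left - 1]))
    if right == len(t) - 1:
        t_right = float(t[-1])
    else:
        frac = (x[right] - half) / (x[right] - x[right + 1])
        t_right = float(t[right] + frac * (t[right + 1] - t[right]))
    return t_right - t_left


def extract_features(trajectory: Trajectory, species: str, basal: float,
                     rel_tol: float = 0.01) -> ResponseFeatures:
    """Assemble the full :class:`ResponseFeatures` record for one observable."""
    pk_t, pk_v, pk_flags = peak(trajectory, species)
    cls, cls_flags = classify_response(trajectory, species, basal)
    if "no_interior_peak" in pk_flags:
        ttb, ttb_flags = float("nan"), ()
    else:
        ttb, ttb_flags = time_to_basal(trajectory, species, basal, rel_tol)
    return ResponseFeatures(
        species=species,
        peak_time=pk_t,
        peak_value=pk_v,
        basal_value=float(basal),
        time_to_basal=ttb,
        terminal_value=float(trajectory[species][-1]),
        response_class=cls,
        rel_tol=rel_tol,
        flags=tuple(pk_flags) + tuple(ttb_flags) + tuple(cls_flags),
    )
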