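"""Scalar-trace analytics: smoothing and characteristic-time extraction.

Single-cell kinetic curves (organelle-droplet distances, synapse
enrichments, orientation angles) are smoothed with Tukey's 3R running
median and reduced to characteristic values: windowed peaks and minima,
plateau levels, gated threshold-crossing ("polarization") times, the last
local minimum of the nucleus-droplet distance, the first frame the
nuclear-invagination angle drops below 45 degrees, and coefficients of
variation of shape metrics.

Crossing detection uses strict inequality at sample points with no
sub-frame interpolation, so extracted times are quantized to the frame
interval — the temporal resolution of the underlying movies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import KineticTrace
from .errors import InvalidParameterError

__all__ = [
    "CharacteristicTimeSpec",
    "CENTROSOME_SPEC",
    "GOLGI_SPEC",
    "LYSOSOME_SPEC",
    "tukey_3r",
    "moving_average",
    "window_extremum",
    "plateau_mean",
    "polarization_time",
    "last_local_min_time",
    "orientation_time",
    "cv_percent",
]


@dataclass(frozen=True)
class CharacteristicTimeSpec:
    """Threshold/gate pair for a gated distance-crossing time.

    ``threshold`` is the distance (um) whose first downward crossing
    defines polarization; the crossing is only scored for cells starting
    above ``start_gate``, so that an approach is actually observable.
    """

    threshold: float
    start_gate: float

    def __post_init__(self) -> None:
        if self.start_gate <= self.threshold:
            raise InvalidParameterError("start_gate must exceed threshold")


# The organelle-specific pairs used throughout the assays (um).
CENTROSOME_SPEC = CharacteristicTimeSpec(threshold=2.0, start_gate=3.0)
GOLGI_SPEC = CharacteristicTimeSpec(threshold=4.0, start_gate=5.0)
LYSOSOME_SPEC = CharacteristicTimeSpec(threshold=3.0, start_gate=4.0)

_MAX_3R_PASSES = 100


def _median3_pass(v: np.ndarray) -> np.ndarray:
    out = v.copy()
    if len(v) >= 3:
        stacked = np.stack([v[:-2], v[1:-1], v[2:]])
        out[1:-1] = np.median(stacked, axis=0)
    return out


def tukey_3r(trace: KineticTrace) -> KineticTrace:
    """Tukey 3R smoothing: running median of 3, repeated to convergence.

    Endpoints are copied unchanged (Tukey's basic "3" smoother).  Median
    smoothing reaches a fixed point quickly; an iteration cap guards the
    loop but is never hit in practice.
    """
    v = np.asarray(trace.values, float)
    if len(v) < 3:
        warnings.warn("trace shorter than 3 samples; 3R smoothing is a no-op")
        return trace.with_values(v)
    for _ in range(_MAX_3R_PASSES):
        nxt = _median3_pass(v)
        if np.array_equal(nxt, v):
            return trace.with_values(nxt)
        v = nxt
    raise RuntimeError("3R smoothing failed to converge")  # pragma: no cover


def moving_average(trace: KineticTrace, window: int = 3) -> KineticTrace:
    """Centered moving average; edges use the truncated available window."""
    if window < 1 or window % 2 == 0:
        raise InvalidParameterError("window must be odd and >= 1")
    v = np.asarray(trace.values, float)
    half = window // 2
    out = np.empty_like(v)
    for i in range(len(v)):
        lo, hi = max(0, i - half), min(len(v), i + half + 1)
        out[i] = v[lo:hi].mean()
    return trace.with_values(out)


def _window_slice(trace: KineticTrace, t_lo: float, t_hi: float) -> np.ndarray:
    sel = (trace.times >= t_lo) & (trace.times <= t_hi)
    if not sel.any():
        raise InvalidParameterError(
            f"window [{t_lo}, {t_hi}] s does not intersect the trace support"
        )
    return sel


def window_extremum(trace: KineticTrace, window: tuple[float, float], kind: str = "max"):
    """Time and value of the extremum of the 3R-smoothed trace in a window.

    Used for e.g. the peak of synapse actin/DAG enrichment in the first
    10 min of contact, or the minimum nucleus distance in 3-10 min.
    Ties resolve to the earliest time.
    """
    if kind not in ("max", "min"):
        raise InvalidParameterError("kind must be 'max' or 'min'")
    sel = _window_slice(trace, *window)
    smooth = tukey_3r(trace).values[sel]
    times = trace.times[sel]
    idx = int(np.argmax(smooth)) if kind == "max" else int(np.argmin(smooth))
    return float(times[idx]), float(smooth[idx])


def plateau_mean(trace: KineticTrace, window: tuple[float, float] = (25 * 60.0, 30 * 60.0)) -> float:
    """Mean of the raw (unsmoothed) values over a closed time window.

    Defaults to the 25-30 min window used for plateau levels of antigen
    recruitment and organelle distances.
    """
    sel = _window_slice(trace, *window)
    return float(trace.values[sel].mean())


def polarization_time(trace: KineticTrace, spec: CharacteristicTimeSpec) -> float | None:
    """Gated first-crossing time of a distance trace, or None.

    The trace is 3R-smoothed first.  Cells whose smoothed starting
    distance is at or below ``start_gate`` are excluded (None): their
    approach cannot be resolved.  Otherwise the first time the smoothed
    distance drops strictly below ``threshold`` is returned; None if it
    never does.
    """
    smooth = tukey_3r(trace).values
    if smooth[0] <= spec.start_gate:
        return None
    below = np.nonzero(smooth < spec.threshold)[0]
    return float(trace.times[below[0]]) if below.size else None


def last_local_min_time(trace: KineticTrace) -> float:
    """Time of the last local minimum of the 3R-smoothed trace.

    Marks the moment after which the nucleus only moves rearward: the
    latest interior sample that is <= both neighbors and < at least one
    (plateau minima count at their last sample).  A trace without an
    interior minimum falls back to its latest global-minimum sample, so a
    monotone decay returns the final time and a monotone rise the first.
    """
    if len(trace) < 3:
        raise InvalidParameterError("need at least 3 samples")
    v = tukey_3r(trace).values
    candidates = [
        i
        for i in range(1, len(v) - 1)
        if v[i] <= v[i - 1] and v[i] <= v[i + 1] and (v[i] < v[i - 1] or v[i] < v[i + 1])
    ]
    if candidates:
        return float(trace.times[candidates[-1]])
    minima = np.nonzero(v == v.min())[0]
    return float(trace.times[minima[-1]])


def orientation_time(angle_trace: KineticTrace, threshold: float = 45.0) -> float | None:
    """First time the 3R-smoothed invagination angle drops below threshold.

    theta_N < 45 degrees means the nuclear invagination faces the immune
    synapse.  None when the angle never crosses.
    """
    smooth = tukey_3r(angle_trace).values
    below = np.nonzero(smooth < threshold)[0]
    return float(angle_trace.times[below[0]]) if below.size else None


def cv_percent(values) -> float:
    """Percent coefficient of variation: 100 * sample s.d. / mean."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise InvalidParameterError("CV needs at least 2 samples")
    m = v.mean()
    if m == 0:
        raise InvalidParameterError("CV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / m)
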