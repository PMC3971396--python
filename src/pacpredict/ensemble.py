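"""Ensemble occupancy of a phase interval, smoothing, and alarm generation.

The per-contact mean coupling phases are reduced to a single scalar time
series: the proportion of contacts whose coupling phase falls inside a
given phase interval ("occupancy").  The circle is partitioned into 11
equal half-open intervals.  The raw proportion is smoothed with a causal
first-order (random-walk) Kalman filter, and an alarm is raised whenever
the smoothed proportion crosses a threshold, subject to a refractory
period equal to the assumed preictal duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coupling import CouplingPhaseMap

__all__ = [
    "PhaseInterval",
    "phase_interval_grid",
    "N_INTERVALS",
    "OccupancySeries",
    "occupancy",
    "kalman_smooth",
    "AlarmSeries",
    "generate_alarms",
    "identify_implicated_contacts",
]

N_INTERVALS = 11

#: Default Kalman parameters: process variance q and observation variance r.
#: With q/r = 0.01 the steady-state gain is ~0.095, i.e. an effective
#: memory of roughly ten one-minute windows, smoothing away single-window
#: fluctuations while following shifts developing over tens of minutes.
KALMAN_Q = 1e-4
KALMAN_R = 1e-2


@dataclass(frozen=True)
class PhaseInterval:
    """Half-open phase interval [lo, hi) on the circle (radians)."""

    lo: float
    hi: float
    index: int = -1

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def contains(self, phi: np.ndarray) -> np.ndarray:
        """Membership test; the last grid interval is closed at pi."""
        phi = np.asarray(phi)
        upper = phi <= self.hi if np.isclose(self.hi, np.pi) else phi < self.hi
        return (phi >= self.lo) & upper


def phase_interval_grid(n_intervals: int = N_INTERVALS) -> list[PhaseInterval]:
    """Equal partition of (-pi, pi] into ``n_intervals`` intervals.

    Intervals are half-open ``[lo, hi)`` starting at -pi, with the final
    interval closed at pi so the grid tiles the circle exactly.
    """
    edges = np.linspace(-np.pi, np.pi, n_intervals + 1)
    return [
        PhaseInterval(lo=float(edges[i]), hi=float(edges[i + 1]), index=i)
        for i in range(n_intervals)
    ]


@dataclass
class OccupancySeries:
    """Per-window proportion of contacts inside one phase interval."""

    raw: np.ndarray
    interval: PhaseInterval
    window_s: float
    smoothed: np.ndarray | None = None

    @property
    def n_windows(self) -> int:
        return self.raw.size

    def times(self) -> np.ndarray:
        """Window start times in seconds."""
        return np.arange(self.n_windows) * self.window_s


def occupancy(
    cmap: CouplingPhaseMap, interval: PhaseInterval
) -> OccupancySeries:
    """Fraction of contacts with coupling phase inside ``interval``.

    Channels whose phase is undefined in a window (NaN) are excluded from
    both numerator and denominator; windows with no defined channel at all
    are flagged NaN.
    """
    phi = cmap.phi_c
    if phi.size == 0:
        raise ValueError("empty coupling map")
    defined = np.isfinite(phi)
    inside = np.zeros_like(phi, dtype=bool)
    inside[defined] = interval.contains(phi[defined])
    n_def = defined.sum(axis=0)
    with np.errstate(invalid="ignore"):
        raw = np.where(n_def > 0, inside.sum(axis=0) / np.maximum(n_def, 1),
                       np.nan)
    return OccupancySeries(raw=raw, interval=interval, window_s=cmap.window_s)


def kalman_smooth(
    raw: np.ndarray, q: float = KALMAN_Q, r: float = KALMAN_R
) -> np.ndarray:
    """Causal first-order Kalman filter for a scalar random-walk state.

    State model ``x_t = x_{t-1} + w`` (variance ``q``), observation
    ``z_t = x_t + v`` (variance ``r``).  Initialized at the first
    observation with variance ``r``.  Purely causal: the estimate at
    window ``t`` uses observations up to ``t`` only.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1:
        raise ValueError("expected a 1-D series")
    if not np.isfinite(raw).all():
        raise ValueError("non-finite values in occupancy series")
    if q <= 0 or r <= 0:
        raise ValueError("variances q and r must be positive")
    out = np.empty_like(raw)
    if raw.size == 0:
        return out
    x, p = raw[0], r
    out[0] = x
    for t in range(1, raw.size):
        p_pred = p + q
        k = p_pred / (p_pred + r)
        x = x + k * (raw[t] - x)
        p = (1.0 - k) * p_pred
        out[t] = x
    return out


@dataclass
class AlarmSeries:
    """Alarm times (seconds from record start) with refractory bookkeeping."""

    alarm_times: np.ndarray
    refractory_s: float
    threshold: float

    @property
    def n_alarms(self) -> int:
        return self.alarm_times.size

    def within(self, span: tuple[float, float]) -> "AlarmSeries":
        lo, hi = span
        keep = (self.alarm_times >= lo) & (self.alarm_times < hi)
        return AlarmSeries(self.alarm_times[keep], self.refractory_s,
                          self.threshold)


def generate_alarms(
    smoothed: np.ndarray,
    threshold: float,
    refractory_s: float,
    window_s: float,
    t0: float = 0.0,
) -> AlarmSeries:
    """Threshold the smoothed occupancy series into alarms.

    An alarm is raised at the start time of every window whose smoothed
    value exceeds ``threshold``, unless a previous alarm lies within
    ``refractory_s`` seconds.  ``t0`` is the absolute time of window 0.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie strictly between 0 and 1")
    smoothed = np.asarray(smoothed, dtype=float)
    above = np.nonzero(smoothed > threshold)[0]
    times = []
    last = -np.inf
    for idx in above:
        t = t0 + idx * window_s
        if t - last >= refractory_s:
            times.append(t)
            last = t
    return AlarmSeries(np.asarray(times, dtype=float), refractory_s, threshold)


def identify_implicated_contacts(
    cmap: CouplingPhaseMap,
    interval: PhaseInterval,
    preictal_windows: np.ndarray,
    interictal_windows: np.ndarray,
) -> set[str]:
    """Channels whose preictal in-interval incidence is >= 2x interictal.

    The incidence rate of a channel is the fraction of windows (within the
    given window set) whose coupling phase falls in ``interval``.  A channel
    is implicated when its preictal rate is at least twice its interictal
    rate (inclusive boundary); channels silent interictally but active
    preictally are implicated as well.
    """
    pre = np.asarray(preictal_windows, dtype=int)
    inter = np.asarray(interictal_windows, dtype=int)
    if pre.size == 0 or inter.size == 0:
        raise ValueError("both window sets must be non-empty")

    def _rates(windows: np.ndarray) -> np.ndarray:
        phi = cmap.phi_c[:, windows]
        defined = np.isfinite(phi)
        inside = np.zeros_like(phi, dtype=bool)
        inside[defined] = interval.contains(phi[defined])
        n_def = defined.sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(
                n_def > 0, inside.sum(axis=1) / np.maximum(n_def, 1), 0.0
            )

    pre_rate = _rates(pre)
    inter_rate = _rates(inter)
    implicated = (pre_rate > 0) & (
        (inter_rate == 0) | (pre_rate >= 2.0 * inter_rate)
    )
    return {cmap.channel_labels[i] for i in np.nonzero(implicated)[0]}
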