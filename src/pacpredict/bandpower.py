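"""Baseline predictor from channel-averaged relative band power.

The control analysis asks whether preictal changes found by the coupling
detector could be explained by ordinary spectral power fluctuations (e.g.
vigilance changes).  The power spectral density of every channel is
estimated over consecutive 5-second windows with the Burg autoregressive
method (order 16), the power in a named band (delta 0.1-4 Hz, theta
4-8 Hz, gamma 30-140 Hz) is normalized by the power over the whole
analyzed range, averaged over channels, and thresholded into alarms with
the same refractory/scoring machinery as the coupling detector (no Kalman
smoothing: the threshold is applied to the raw channel-averaged series).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as sp_fft

from .ensemble import AlarmSeries, generate_alarms
from .evaluation import PerformanceResult, score_alarms
from .io import Recording

__all__ = [
    "POWER_BANDS",
    "DegenerateSignalError",
    "burg_psd",
    "RelativePowerSeries",
    "relative_band_power",
    "power_detector",
    "power_sensitivity_at_matched_fpr",
]

#: Analysis bands of the power baseline (Hz).  These are the baseline's own
#: band definitions and intentionally differ from the coupling bands.
POWER_BANDS = {"delta": (0.1, 4.0), "theta": (4.0, 8.0), "gamma": (30.0, 140.0)}

AR_ORDER = 16
POWER_WINDOW_S = 5.0
_NFFT = 4096


class DegenerateSignalError(ValueError):
    """Raised when a window is too degenerate for an AR fit (e.g. constant)."""


def _burg_batch(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Burg AR coefficients for a batch of windows.

    ``x`` has shape ``(m, n)``; returns ``(a, sigma2)`` where ``a`` of
    shape ``(m, order)`` holds the coefficients of the prediction-error
    polynomial ``A(z) = 1 + a1 z^-1 + ... + ap z^-p`` and ``sigma2`` the
    driving-noise variance.  Vectorized lattice (Levinson) recursion over
    windows; numerically identical to the classic per-window algorithm.
    """
    x = np.asarray(x, dtype=np.float64)
    m, n = x.shape
    if n < 2 * order:
        raise ValueError("window shorter than twice the AR order")
    x = x - x.mean(axis=1, keepdims=True)
    f = x[:, 1:].copy()
    b = x[:, :-1].copy()
    a = np.zeros((m, order))
    sigma2 = (x * x).sum(axis=1) / n
    for k in range(order):
        den = (f * f).sum(axis=1) + (b * b).sum(axis=1)
        if np.any(den <= 0):
            raise DegenerateSignalError("degenerate AR fit (constant window)")
        refl = -2.0 * (f * b).sum(axis=1) / den
        if k > 0:
            a[:, :k] = a[:, :k] + refl[:, None] * a[:, k - 1 :: -1]
        a[:, k] = refl
        sigma2 = sigma2 * (1.0 - refl**2)
        if k < order - 1:
            f, b = (
                f[:, 1:] + refl[:, None] * b[:, 1:],
                b[:, :-1] + refl[:, None] * f[:, :-1],
            )
    return a, sigma2


def burg_psd(
    x: np.ndarray, fs: float, order: int = AR_ORDER, nfft: int = _NFFT
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Burg power spectral density of a single window.

    Returns ``(freqs, psd)`` over ``[0, fs/2]``.  The PSD integrates
    (trapezoidally) to approximately the signal variance.  A constant or
    zero window has no meaningful AR fit and raises
    :class:`DegenerateSignalError`.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("expected a single 1-D window")
    if np.ptp(x) == 0:
        raise DegenerateSignalError("constant window")
    a, sigma2 = _burg_batch(x[None, :], order)
    freqs, psd = _psd_from_ar(a, sigma2, fs, nfft)
    return freqs, psd[0]


def _psd_from_ar(
    a: np.ndarray, sigma2: np.ndarray, fs: float, nfft: int
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate one-sided AR spectra on the rfft grid."""
    m, order = a.shape
    poly = np.zeros((m, nfft))
    poly[:, 0] = 1.0
    poly[:, 1 : order + 1] = a
    denom = np.abs(sp_fft.rfft(poly, axis=1)) ** 2
    psd = sigma2[:, None] / (fs * denom)
    psd[:, 1:-1] *= 2.0  # fold negative frequencies
    freqs = sp_fft.rfftfreq(nfft, d=1.0 / fs)
    return freqs, psd


@dataclass
class RelativePowerSeries:
    """Channel-averaged relative power of one band in 5-s windows."""

    band: str
    band_hz: tuple[float, float]
    values: np.ndarray  # NaN where every channel was degenerate
    window_s: float

    @property
    def n_windows(self) -> int:
        return self.values.size


def _band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    return (freqs >= band[0]) & (freqs <= band[1])


def relative_band_power(
    recording: Recording,
    band: str,
    window_s: float = POWER_WINDOW_S,
    order: int = AR_ORDER,
    nfft: int = _NFFT,
) -> RelativePowerSeries:
    """Band power relative to the whole analyzed range, channel-averaged.

    The normalizing "whole range" spans 0.1 Hz to
    ``min(140, 0.9 * Nyquist)`` Hz — the widest band the pipeline analyzes.
    Degenerate windows (no AR fit) are dropped from the channel average and
    NaN is reported if every channel is degenerate.
    """
    band_hz = POWER_BANDS[band]
    fs = recording.fs
    total_hz = (0.1, min(140.0, 0.45 * fs))
    wlen = int(round(window_s * fs))
    n_win = recording.n_samples // wlen
    if n_win == 0:
        raise ValueError("recording shorter than one power window")

    freqs = sp_fft.rfftfreq(nfft, d=1.0 / fs)
    in_band = _band_mask(freqs, band_hz)
    in_total = _band_mask(freqs, total_hz)

    acc = np.zeros(n_win)
    n_ok = np.zeros(n_win)
    for ch in range(recording.n_channels):
        wins = recording.signals[ch, : n_win * wlen].reshape(n_win, wlen)
        ptp = wins.max(axis=1) - wins.min(axis=1)
        ok = ptp > 0
        if not ok.any():
            continue
        a, sigma2 = _burg_batch(wins[ok], order)
        _, psd = _psd_from_ar(a, sigma2, fs, nfft)
        num = np.trapezoid(psd[:, in_band], freqs[in_band], axis=1)
        den = np.trapezoid(psd[:, in_total], freqs[in_total], axis=1)
        rel = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
        good = ok.copy()
        good[ok] &= np.isfinite(rel)
        acc[good] += rel[np.isfinite(rel)]
        n_ok[good] += 1
    with np.errstate(invalid="ignore"):
        values = np.where(n_ok > 0, acc / np.maximum(n_ok, 1), np.nan)
    return RelativePowerSeries(band, band_hz, values, window_s)


def power_detector(
    recording: Recording,
    band: str,
    threshold: float,
    sop_min: float,
    span: tuple[float, float] | None = None,
    series: RelativePowerSeries | None = None,
) -> tuple[AlarmSeries, PerformanceResult]:
    """Threshold the relative-power series into alarms and score them.

    Uses the identical alarm/refractory/scoring machinery as the coupling
    detector, applied to the raw channel-averaged series.
    """
    if series is None:
        series = relative_band_power(recording, band)
    values = series.values
    if np.isnan(values).any():
        import pandas as pd

        values = pd.Series(values).ffill().bfill().to_numpy()
    alarms = generate_alarms(
        values, threshold, refractory_s=sop_min * 60.0,
        window_s=series.window_s,
    )
    if span is None:
        span = (0.0, recording.duration)
    perf = score_alarms(
        alarms.within(span), recording.seizure_onsets, sop_min, span
    )
    return alarms, perf


def power_sensitivity_at_matched_fpr(
    recording: Recording,
    band: str,
    sop_min: float,
    span: tuple[float, float],
    fpr_budget: float,
    n_thresholds: int = 60,
    series: RelativePowerSeries | None = None,
) -> float:
    """Best attainable baseline sensitivity at an FPR budget.

    Sweeps thresholds over the quantiles of the power series and returns
    the highest test-span sensitivity among operating points whose FPR does
    not exceed ``fpr_budget`` (5% slack).  Giving the baseline its best
    in-span threshold makes this an upper bound on what a trained power
    detector could achieve at the matched rate.
    """
    if series is None:
        series = relative_band_power(recording, band)
    finite = series.values[np.isfinite(series.values)]
    qs = np.linspace(0.30, 0.999, n_thresholds)
    thresholds = np.unique(np.quantile(finite, qs))
    best = 0.0
    for thr in thresholds:
        if not 0 < thr < 1:
            continue
        _, perf = power_detector(
            recording, band, float(thr), sop_min, span, series=series
        )
        if perf.fpr <= fpr_budget * 1.05 + 1e-12 and np.isfinite(perf.ss):
            best = max(best, perf.ss)
    return best
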