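"""Prospective train/test evaluation and statistical validation.

The detector is optimized per patient on a training span (the first
``n_train`` seizures and at least ``min_train_h`` hours of recording) by
exhaustive search over the coupling band pair, the phase interval, the
assumed preictal duration (SOP) and the occupancy threshold.  The frozen
configuration is then applied unchanged to the remaining test span.

Performance is scored as sensitivity (SS, fraction of seizures preceded by
at least one alarm within the SOP) and false prediction rate (FPR, false
alarms per hour, where the denominator excludes preictal windows and time
already spent under false warning).  Chance level is established by a
random predictor raising alarms as a Poisson process at the observed FPR;
a patient is significant when SS exceeds the critical random-predictor
sensitivity sigma_rand at alpha = 0.01.  Group-level significance is the
upper-tail binomial probability of observing as many significant patients
under the per-patient null rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .coupling import BandPair, CouplingPhaseMap, STANDARD_PAIRS, coupling_phase_maps
from .ensemble import (
    KALMAN_Q,
    KALMAN_R,
    AlarmSeries,
    PhaseInterval,
    generate_alarms,
    kalman_smooth,
    occupancy,
    phase_interval_grid,
)
from .io import Recording

__all__ = [
    "DetectorConfig",
    "PerformanceResult",
    "SignificanceResult",
    "ParameterGrid",
    "split_train_test",
    "score_alarms",
    "optimize_parameters",
    "OptimizationResult",
    "run_detector",
    "evaluate_patient",
    "PatientResult",
    "random_predictor_sensitivity",
    "group_significance",
    "load_reference_table",
    "summarize_results_table",
]

SOP_GRID_MIN = (10, 30, 60)
DEFAULT_ALPHA = 0.01  # per-patient random-predictor level
FPR_REF = 1.0  # false alarms/h normalizing the optimization distance


@dataclass(frozen=True)
class DetectorConfig:
    """A frozen detector parameterization."""

    pair: BandPair
    interval: PhaseInterval
    sop_min: int
    threshold: float

    @property
    def refractory_s(self) -> float:
        """Refractory period after an alarm equals the preictal duration."""
        return self.sop_min * 60.0


@dataclass
class PerformanceResult:
    """Sensitivity / false-prediction-rate bookkeeping for one span."""

    ss: float
    fpr: float
    n_seizures: int
    n_true_alarms: int
    n_false_alarms: int
    denominator_h: float


@dataclass
class SignificanceResult:
    sigma_rand: float
    alpha: float
    significant: bool


@dataclass
class ParameterGrid:
    """Search space of the training-phase optimization."""

    pairs: list[BandPair]
    intervals: list[PhaseInterval] = field(default_factory=phase_interval_grid)
    sop_min_grid: tuple[int, ...] = SOP_GRID_MIN
    thresholds: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(5, 51) / 100.0, 2)
    )

    @classmethod
    def standard(cls, fs: float) -> "ParameterGrid":
        return cls(pairs=STANDARD_PAIRS(fs))


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------


def split_train_test(
    recording: Recording,
    n_train_seizures: int = 4,
    min_train_h: float = 10.0,
    sop_max_min: int = max(SOP_GRID_MIN),
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Split a recording into contiguous training and testing spans.

    The training span covers the first ``n_train_seizures`` seizures plus
    the longest candidate preictal duration, and at least ``min_train_h``
    hours.  Returns ``((0, t_split), (t_split, duration))`` in seconds.
    """
    onsets = recording.seizure_onsets
    if onsets.size < n_train_seizures + 1:
        raise ValueError(
            f"patient unevaluable: needs > {n_train_seizures} seizures, "
            f"has {onsets.size}"
        )
    t_split = max(
        onsets[n_train_seizures - 1] + sop_max_min * 60.0,
        min_train_h * 3600.0,
    )
    if t_split >= recording.duration:
        raise ValueError("training span would consume the whole recording")
    return (0.0, t_split), (t_split, recording.duration)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def _union_length(intervals: list[tuple[float, float]]) -> float:
    """Total length of a union of (lo, hi) intervals."""
    total = 0.0
    last_end = -np.inf
    for lo, hi in sorted(intervals):
        if hi <= last_end:
            continue
        total += hi - max(lo, last_end)
        last_end = hi
    return total


def score_alarms(
    alarms: AlarmSeries,
    seizure_onsets: np.ndarray,
    sop_min: float,
    span: tuple[float, float],
) -> PerformanceResult:
    """Score alarms against seizure onsets over an evaluation span.

    A seizure is predicted when at least one alarm falls in
    ``[onset - SOP, onset)``; an alarm is false when no onset falls in
    ``(t, t + SOP]``.  The FPR denominator is the span duration minus all
    preictal windows and minus the time spent under false warning (the
    refractory tail of each false alarm), in hours.
    """
    lo, hi = span
    if hi <= lo:
        raise ValueError("empty evaluation span")
    sop_s = sop_min * 60.0
    onsets = np.asarray(seizure_onsets, dtype=float)
    onsets = onsets[(onsets >= lo) & (onsets < hi)]
    times = alarms.alarm_times
    times = times[(times >= lo) & (times < hi)]

    predicted = np.zeros(onsets.size, dtype=bool)
    is_true_alarm = np.zeros(times.size, dtype=bool)
    for i, t in enumerate(times):
        hits = (onsets > t) & (onsets <= t + sop_s)
        if hits.any():
            is_true_alarm[i] = True
            predicted |= hits

    pre = [(max(o - sop_s, lo), min(o, hi)) for o in onsets]
    pre_len = _union_length(pre)
    false_warn = [
        (t, min(t + sop_s, hi)) for t in times[~is_true_alarm]
    ]
    # false-warning time not already inside a preictal window
    false_len = _union_length(pre + false_warn) - pre_len

    denom_h = ((hi - lo) - pre_len - false_len) / 3600.0
    if denom_h <= 0:
        raise ValueError("non-positive FPR denominator")
    n_false = int((~is_true_alarm).sum())
    ss = float(predicted.sum() / onsets.size) if onsets.size else float("nan")
    return PerformanceResult(
        ss=ss,
        fpr=n_false / denom_h,
        n_seizures=int(onsets.size),
        n_true_alarms=int(is_true_alarm.sum()),
        n_false_alarms=n_false,
        denominator_h=denom_h,
    )


# ---------------------------------------------------------------------------
# Detector pipeline and optimization
# ---------------------------------------------------------------------------


def run_detector(
    cmap: CouplingPhaseMap,
    config: DetectorConfig,
    q: float = KALMAN_Q,
    r: float = KALMAN_R,
    t0: float = 0.0,
) -> AlarmSeries:
    """Occupancy -> Kalman smoothing -> thresholding with refractory."""
    occ = occupancy(cmap, config.interval)
    raw = occ.raw
    if np.isnan(raw).any():  # windows with no defined channel: carry forward
        raw = pd.Series(raw).ffill().bfill().to_numpy()
    smoothed = kalman_smooth(raw, q=q, r=r)
    return generate_alarms(
        smoothed,
        threshold=config.threshold,
        refractory_s=config.refractory_s,
        window_s=cmap.window_s,
        t0=t0,
    )


@dataclass
class OptimizationResult:
    config: DetectorConfig
    train_performance: PerformanceResult
    distance: float


def optimize_parameters(
    train_recording: Recording | None,
    grid: ParameterGrid | None = None,
    *,
    maps: dict[str, CouplingPhaseMap] | None = None,
    seizure_onsets: np.ndarray | None = None,
    span: tuple[float, float] | None = None,
    window_s: float = 60.0,
    q: float = KALMAN_Q,
    r: float = KALMAN_R,
    fpr_ref: float = FPR_REF,
) -> OptimizationResult:
    """Exhaustive grid search minimizing the distance to perfect performance.

    ``d = sqrt((1 - SS)^2 + (FPR / fpr_ref)^2)`` with ``fpr_ref`` = 1/h.
    Ties are broken by lower FPR, then higher SS, then the deterministic
    grid order (pair, interval, SOP, threshold).  Configurations producing
    no alarm score SS = 0.

    Coupling maps may be passed precomputed (``maps``, keyed by pair code)
    to avoid re-filtering; otherwise they are computed from
    ``train_recording`` over ``span``.
    """
    if grid is None:
        if train_recording is None:
            raise ValueError("need a recording or an explicit grid")
        grid = ParameterGrid.standard(train_recording.fs)
    if maps is None:
        if train_recording is None:
            raise ValueError("need a recording when maps are not given")
        fs = train_recording.fs
        stop = (
            int(round(span[1] * fs)) if span is not None
            else train_recording.n_samples
        )
        maps = coupling_phase_maps(
            train_recording, grid.pairs, window_s, sample_range=(0, stop)
        )
    if seizure_onsets is None:
        seizure_onsets = train_recording.seizure_onsets
    if span is None:
        first = next(iter(maps.values()))
        span = (0.0, first.n_windows * first.window_s)

    best = None
    for pair in grid.pairs:
        cmap = maps[pair.code]
        for interval in grid.intervals:
            occ = occupancy(cmap, interval)
            raw = occ.raw
            if np.isnan(raw).any():
                raw = pd.Series(raw).ffill().bfill().to_numpy()
            smoothed = kalman_smooth(raw, q=q, r=r)
            for sop in grid.sop_min_grid:
                for thr in grid.thresholds:
                    alarms = generate_alarms(
                        smoothed, float(thr), sop * 60.0, cmap.window_s
                    )
                    try:
                        perf = score_alarms(alarms, seizure_onsets, sop, span)
                    except ValueError:
                        # constant alarming consumed the whole denominator
                        continue
                    ss = 0.0 if np.isnan(perf.ss) else perf.ss
                    d = float(np.hypot(1.0 - ss, perf.fpr / fpr_ref))
                    key = (d, perf.fpr, -ss)
                    if best is None or key < best[0]:
                        cfg = DetectorConfig(pair, interval, sop, float(thr))
                        best = (key, OptimizationResult(cfg, perf, d))
    return best[1]


@dataclass
class PatientResult:
    """Full prospective evaluation of one recording."""

    config: DetectorConfig
    train: PerformanceResult
    test: PerformanceResult
    significance: SignificanceResult
    train_span: tuple[float, float]
    test_span: tuple[float, float]


def evaluate_patient(
    recording: Recording,
    n_train_seizures: int = 4,
    min_train_h: float = 10.0,
    window_s: float = 60.0,
    alpha: float = DEFAULT_ALPHA,
    q: float = KALMAN_Q,
    r: float = KALMAN_R,
    grid: ParameterGrid | None = None,
) -> PatientResult:
    """Train on the leading span, freeze the detector, test prospectively."""
    train_span, test_span = split_train_test(
        recording, n_train_seizures, min_train_h
    )
    if grid is None:
        grid = ParameterGrid.standard(recording.fs)
    maps = coupling_phase_maps(recording, grid.pairs, window_s)
    onsets = recording.seizure_onsets

    opt = optimize_parameters(
        None,
        grid,
        maps=maps,
        seizure_onsets=onsets[onsets < train_span[1]],
        span=train_span,
        window_s=window_s,
        q=q,
        r=r,
    )
    cfg = opt.config
    alarms = run_detector(maps[cfg.pair.code], cfg, q=q, r=r)
    test_perf = score_alarms(
        alarms.within(test_span), onsets, cfg.sop_min, test_span
    )
    sigma = random_predictor_sensitivity(
        test_perf.fpr, cfg.sop_min, max(test_perf.n_seizures, 1), alpha
    )
    sig = SignificanceResult(
        sigma_rand=sigma,
        alpha=alpha,
        significant=bool(
            np.isfinite(test_perf.ss) and test_perf.ss > sigma
        ),
    )
    return PatientResult(cfg, opt.train_performance, test_perf, sig,
                         train_span, test_span)


# ---------------------------------------------------------------------------
# Random predictor and group statistics
# ---------------------------------------------------------------------------


def random_predictor_sensitivity(
    fpr: float, sop_min: float, K: int, alpha: float = DEFAULT_ALPHA
) -> float:
    """Critical sensitivity sigma_rand of the chance-level predictor.

    A random predictor raising alarms as a Poisson process at rate ``fpr``
    predicts a given seizure with probability
    ``P = 1 - exp(-fpr * SOP)`` (at least one alarm in the preictal
    window).  sigma_rand is the smallest k/K whose binomial upper-tail
    probability falls below ``alpha``; an actual detector must exceed it
    at matched FPR and SOP to beat chance.  Returns 1.0 when even
    predicting all K seizures would not be significant.
    """
    if fpr < 0:
        raise ValueError("fpr must be non-negative")
    if K < 1:
        raise ValueError("K must be at least 1")
    p = 1.0 - np.exp(-fpr * sop_min / 60.0)
    for k in range(1, K + 1):
        if stats.binom.sf(k - 1, K, p) < alpha:
            return k / K
    return 1.0


def group_significance(n_sig: int, N: int, alpha_patient: float) -> float:
    """Upper-tail binomial probability of >= ``n_sig`` significant patients.

    Under the null that every patient independently beats the random
    predictor with probability ``alpha_patient``, returns
    ``Pr[Binom(N, alpha_patient) >= n_sig]``.
    """
    if not 0 <= n_sig <= N:
        raise ValueError("need 0 <= n_sig <= N")
    return float(stats.binom.sf(n_sig - 1, N, alpha_patient))


# ---------------------------------------------------------------------------
# Reporting aggregates
# ---------------------------------------------------------------------------


def load_reference_table() -> pd.DataFrame:
    """Packaged per-patient training/testing parameter and performance table."""
    with resources.files("pacpredict.data").joinpath(
        "reference_table.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    df["significant"] = df["significant"].astype(bool)
    df["power_significant"] = df["power_significant"].fillna("---")
    return df


def _focus_groups(focus: str) -> set[str]:
    """Lobe codes present in a focus string such as ``'fbr,tml'``."""
    return {part.strip()[0] for part in focus.split(",") if part.strip()}


def summarize_results_table(table: pd.DataFrame) -> dict:
    """Aggregate per-patient rows into the group-level report.

    Means and ranges are over the significant patients; a patient whose
    focus spans both frontal and temporal lobes counts in both groups.
    """
    if table.empty:
        raise ValueError("empty results table")
    sig = table[table["significant"]]
    n_sig, n_pat = len(sig), len(table)

    def _stats(rows: pd.DataFrame) -> dict:
        return {
            "n": len(rows),
            "mean_ss_pct": float(rows["test_ss_pct"].mean()),
            "range_ss_pct": (
                float(rows["test_ss_pct"].min()),
                float(rows["test_ss_pct"].max()),
            ),
            "mean_fpr_per_h": float(rows["test_fpr_per_h"].mean()),
            "range_fpr_per_h": (
                float(rows["test_fpr_per_h"].min()),
                float(rows["test_fpr_per_h"].max()),
            ),
        }

    groups = table["focus"].map(_focus_groups)
    temporal = sig[groups.loc[sig.index].map(lambda g: "t" in g)]
    frontal = sig[groups.loc[sig.index].map(lambda g: "f" in g)]
    power = table["power_significant"].fillna("---")
    report = {
        "n_patients": n_pat,
        "n_significant": n_sig,
        "significant_ids": sig["id"].tolist(),
        "significant": _stats(sig) if n_sig else None,
        "sop_counts": sig["sop_min"].value_counts().to_dict(),
        "band_counts": sig["band"].value_counts().to_dict(),
        "temporal_group": _stats(temporal) if len(temporal) else None,
        "frontal_group": _stats(frontal) if len(frontal) else None,
        "power_band_counts": {
            "delta": int((power.str[0] == "*").sum()),
            "theta": int((power.str[1] == "*").sum()),
            "gamma": int((power.str[2] == "*").sum()),
        },
        "group_p": group_significance(n_sig, n_pat, 0.05),
    }
    return report
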