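"""Decoding features: slow movement fields and band powers.

The slow movement field (SMF) of a 500-ms window is the per-channel time
average, z-scored against baseline statistics estimated from the initial
50 s of the session, restricted to the 84 parietal sensors.  Band powers
(alpha 8-13 Hz, beta 13-30 Hz, high-gamma 80-150 Hz) come from the discrete
Fourier transform of the same window and are z-scored against the
distribution of 500-ms band powers over the same 50-s baseline (sliding
windows, 100-ms hop).

Window labelling is causal: a feature labelled t covers [t - 500 ms, t), so
the real-time path never uses future samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateChannelError,
    InsufficientBaselineError,
    WindowBoundsError,
)
from .simulate import MEGSession

WINDOW_MS = 500.0
BASELINE_S = 50.0
BANDS = {
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "high_gamma": (80.0, 150.0),
}
KINDS = ("smf", "alpha", "beta", "high_gamma")


@dataclass(frozen=True)
class WindowGrid:
    """Cue-relative window-end times in milliseconds."""

    start_ms: float = -2000.0
    end_ms: float = 1000.0
    step_ms: float = 100.0

    def __post_init__(self):
        if self.step_ms <= 0:
            raise ValueError("step_ms must be > 0")
        if self.start_ms >= self.end_ms:
            raise ValueError("start_ms must be < end_ms")

    def ends(self) -> np.ndarray:
        n = int(round((self.end_ms - self.start_ms) / self.step_ms))
        return self.start_ms + self.step_ms * np.arange(n + 1)


@dataclass
class BaselineStats:
    """Per-channel baseline moments from the initial 50 s of a session.

    Raw-signal mean/SD feed the SMF; per-band window-power mean/SD (computed
    lazily) feed the band-power features.
    """

    mean: np.ndarray
    sd: np.ndarray
    n_samples: int
    band_stats: dict = field(default_factory=dict)  # band -> (mean, sd)


def compute_baseline_stats(
    session: MEGSession, baseline_s: float = BASELINE_S
) -> BaselineStats:
    """Mean and SD per channel over exactly [0, baseline_s)."""
    n = int(round(baseline_s * session.rate))
    if session.n_samples < n:
        raise InsufficientBaselineError(
            f"session has {session.duration_s:.1f} s; baseline needs "
            f"{baseline_s:.0f} s"
        )
    seg = session.data[:, :n]
    mean = seg.mean(axis=1)
    sd = seg.std(axis=1)
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        raise DegenerateChannelError(bad)
    return BaselineStats(mean=mean, sd=sd, n_samples=n)


@dataclass(frozen=True)
class FeatureWindow:
    """One 500-ms feature vector over the 84 parietal sensors."""

    kind: str
    values: np.ndarray
    window_end_ms: float


def _window_slice(session: MEGSession, window_end_ms: float) -> slice:
    n_win = int(round(WINDOW_MS * session.rate / 1000.0))
    i_end = int(round(window_end_ms * session.rate / 1000.0))
    i_start = i_end - n_win
    if i_start < 0 or i_end > session.n_samples:
        raise WindowBoundsError(
            f"window [{window_end_ms - WINDOW_MS:.0f}, {window_end_ms:.0f}) "
            "ms lies outside the session"
        )
    return slice(i_start, i_end)


def compute_smf(
    session: MEGSession,
    stats: BaselineStats,
    window_end_ms: float,
) -> FeatureWindow:
    """SMF of the causal window ending at ``window_end_ms`` (session time)."""
    sl = _window_slice(session, window_end_ms)
    win_mean = session.data[:, sl].mean(axis=1)
    z = (win_mean - stats.mean) / stats.sd
    mask = session.sensor_array.parietal_mask
    return FeatureWindow(kind="smf", values=z[mask],
                         window_end_ms=float(window_end_ms))


def window_band_power(
    x: np.ndarray, band: str, rate: float, baseline_mean: np.ndarray | None = None
) -> np.ndarray:
    """Summed one-sided DFT power of each channel within a frequency band.

    The window is detrended by the baseline mean (not its own mean), so the
    DC bin carries any slow offset; band edges are half-open [lo, hi).
    Scaling is such that summing over all one-sided bins of a zero-mean
    window returns its variance times the window length (Parseval).
    """
    x = np.atleast_2d(x)
    if baseline_mean is not None:
        x = x - np.asarray(baseline_mean).reshape(-1, 1)
    n = x.shape[1]
    spec = np.fft.rfft(x, axis=1)
    power = np.abs(spec) ** 2 / n
    # one-sided doubling (DC and Nyquist appear once)
    mult = np.full(power.shape[1], 2.0)
    mult[0] = 1.0
    if n % 2 == 0:
        mult[-1] = 1.0
    power = power * mult
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    lo, hi = BANDS[band]
    sel = (freqs >= lo) & (freqs < hi)
    return power[:, sel].sum(axis=1)


def _ensure_band_baseline(
    session: MEGSession, stats: BaselineStats, band: str,
    hop_ms: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean/SD of 500-ms window band powers over the 50-s baseline."""
    if band in stats.band_stats:
        return stats.band_stats[band]
    rate = session.rate
    n_win = int(round(WINDOW_MS * rate / 1000.0))
    hop = int(round(hop_ms * rate / 1000.0))
    ends = np.arange(n_win, stats.n_samples + 1, hop)
    powers = np.empty((len(ends), session.sensor_array.n_sensors))
    for k, e in enumerate(ends):
        powers[k] = window_band_power(
            session.data[:, e - n_win:e], band, rate, stats.mean)
    mean = powers.mean(axis=0)
    sd = powers.std(axis=0)
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        raise DegenerateChannelError(bad)
    stats.band_stats[band] = (mean, sd)
    return mean, sd


def compute_band_power(
    session: MEGSession,
    stats: BaselineStats,
    window_end_ms: float,
    band: str,
    zscore: bool = True,
) -> FeatureWindow:
    """Band power of the causal window ending at ``window_end_ms``.

    With ``zscore`` (the default) the raw summed power is standardized
    against the baseline distribution of 500-ms window powers, making band
    features commensurate with the SMF.
    """
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}; choose from {list(BANDS)}")
    sl = _window_slice(session, window_end_ms)
    raw = window_band_power(session.data[:, sl], band, session.rate,
                            stats.mean)
    mask = session.sensor_array.parietal_mask
    if not zscore:
        return FeatureWindow(kind=band, values=raw[mask],
                             window_end_ms=float(window_end_ms))
    mean, sd = _ensure_band_baseline(session, stats, band)
    z = (raw - mean) / sd
    return FeatureWindow(kind=band, values=z[mask],
                         window_end_ms=float(window_end_ms))


def compute_feature(
    session: MEGSession,
    stats: BaselineStats,
    window_end_ms: float,
    kind: str,
) -> FeatureWindow:
    if kind == "smf":
        return compute_smf(session, stats, window_end_ms)
    return compute_band_power(session, stats, window_end_ms, kind)


def trial_feature_array(
    session: MEGSession,
    stats: BaselineStats,
    grid: WindowGrid,
    kind: str = "smf",
) -> tuple[np.ndarray, np.ndarray]:
    """Features for every cue on the grid.

    Returns (X, ends) with X of shape (n_trials, n_windows, 84); window ends
    are cue-relative, converted internally to session time per trial.
    """
    ends = grid.ends()
    cues = session.schedule.cue_times
    x = np.empty((len(cues), len(ends),
                  int(session.sensor_array.parietal_mask.sum())))
    for i, t_cue in enumerate(cues):
        for j, e in enumerate(ends):
            fw = compute_feature(session, stats, t_cue * 1000.0 + e, kind)
            x[i, j] = fw.values
    return x, ends
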