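"""Statistical-moment features on baseline-corrected stimulation segments.

The four features - mean, variance, skewness, kurtosis - are computed on the
baseline-corrected d[O2Hb] stimulation trace restricted to an analysis
window.  Windows are half-open ``[start, end)`` in onset-relative seconds
(0 = stimulation onset), so a window holds exactly ``(end-start) * rate``
samples.

Default moment conventions (all switchable): unbiased (n-1) variance,
adjusted Fisher-Pearson sample skewness, and sample EXCESS kurtosis (a
normal distribution scores 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .epochs_stats import TrialEpoch

FEATURE_NAMES = ("mean", "variance", "skewness", "kurtosis")


@dataclass(frozen=True, order=True)
class AnalysisWindow:
    """Half-open onset-relative interval [start, end), integer seconds."""

    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("window end must exceed start")
        if self.start < 0:
            raise ValueError("window start must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FeatureVector:
    """Computed feature values; undefined entries are NaN and flagged."""

    values: dict
    undefined: frozenset
    trial: int | None = None
    channel: int | None = None
    window: AnalysisWindow | None = None

    def as_array(self, order: Sequence[str] = FEATURE_NAMES) -> np.ndarray:
        return np.array([self.values.get(name, np.nan) for name in order])


def enumerate_windows(start_range: tuple = (1, 11),
                      end_range: tuple = (5, 15)) -> list[AnalysisWindow]:
    """All (start, end) pairs on the 1-s grid with end > start.

    Defaults give starts 1..11 s and ends 5..15 s (93 windows), ordered by
    start then end.
    """
    out = []
    for start in range(start_range[0], start_range[1] + 1):
        for end in range(end_range[0], end_range[1] + 1):
            if end > start:
                out.append(AnalysisWindow(start, end))
    return out


def _window_slice(window: AnalysisWindow, rate: float) -> slice:
    i0 = int(round(window.start * rate))
    i1 = int(round(window.end * rate))
    return slice(i0, i1)


def extract(ep: TrialEpoch, window: AnalysisWindow,
            wanted: Iterable[str] = FEATURE_NAMES, *,
            excess_kurtosis: bool = True, bias: bool = False) -> FeatureVector:
    """Compute the requested moments on one epoch's corrected trace.

    Skewness and kurtosis are undefined (NaN, flagged) when the window has
    zero spread; mean and variance are still returned.
    """
    wanted = tuple(wanted)
    unknown = set(wanted) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown features {sorted(unknown)}")
    x = ep.corrected_stim[_window_slice(window, ep.sampling_rate)]
    if len(x) < 4:
        raise ValueError("window must contain at least 4 samples")
    if window.end * ep.sampling_rate > len(ep.corrected_stim) + 1e-9:
        raise ValueError("window extends past the stimulation segment")

    ddof = 0 if bias else 1
    values: dict = {}
    undefined: set = set()
    spread = x.std(ddof=0)
    if "mean" in wanted:
        values["mean"] = float(x.mean())
    if "variance" in wanted:
        values["variance"] = float(x.var(ddof=ddof))
    if "skewness" in wanted:
        if spread == 0:
            values["skewness"] = np.nan
            undefined.add("skewness")
        else:
            values["skewness"] = float(sps.skew(x, bias=bias))
    if "kurtosis" in wanted:
        if spread == 0:
            values["kurtosis"] = np.nan
            undefined.add("kurtosis")
        else:
            values["kurtosis"] = float(sps.kurtosis(x, fisher=excess_kurtosis, bias=bias))
    return FeatureVector(values=values, undefined=frozenset(undefined),
                         trial=ep.trial, channel=ep.channel, window=window)


def feature_matrix(epochs: Sequence[TrialEpoch],
                   windows: Sequence[AnalysisWindow] | None = None, *,
                   excess_kurtosis: bool = True, bias: bool = False):
    """Vectorised features for every (channel, window, trial).

    Returns ``(F, labels, channels, windows)`` where ``F`` has shape
    ``(n_channels, n_windows, n_trials, 4)`` in :data:`FEATURE_NAMES` order
    and ``labels`` is the condition label per trial.
    """
    if windows is None:
        windows = enumerate_windows()
    channels = sorted({e.channel for e in epochs})
    trials = sorted({e.trial for e in epochs})
    trial_pos = {t: i for i, t in enumerate(trials)}
    rate = epochs[0].sampling_rate
    n_stim = min(len(e.corrected_stim) for e in epochs)

    traces = np.full((len(channels), len(trials), n_stim), np.nan)
    labels = np.empty(len(trials), dtype=object)
    for e in epochs:
        traces[channels.index(e.channel), trial_pos[e.trial]] = e.corrected_stim[:n_stim]
        labels[trial_pos[e.trial]] = e.condition

    F = np.empty((len(channels), len(windows), len(trials), 4))
    for wi, win in enumerate(windows):
        x = traces[:, :, _window_slice(win, rate)]
        ddof = 0 if bias else 1
        F[:, wi, :, 0] = x.mean(axis=-1)
        F[:, wi, :, 1] = x.var(axis=-1, ddof=ddof)
        spread = x.std(axis=-1, ddof=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sk = sps.skew(x, axis=-1, bias=bias)
            ku = sps.kurtosis(x, axis=-1, fisher=excess_kurtosis, bias=bias)
        sk = np.where(spread == 0, np.nan, sk)
        ku = np.where(spread == 0, np.nan, ku)
        F[:, wi, :, 2] = sk
        F[:, wi, :, 3] = ku
    return F, labels, channels, list(windows)


def features_frame(epochs: Sequence[TrialEpoch],
                   windows: Sequence[AnalysisWindow] | None = None,
                   subject=None, **kw) -> pd.DataFrame:
    """Long-format export of the full feature grid (one row per combination)."""
    F, labels, channels, windows = feature_matrix(epochs, windows, **kw)
    rows = []
    for ci, ch in enumerate(channels):
        for wi, win in enumerate(windows):
            for ti in range(len(labels)):
                rows.append({
                    "subject": subject, "trial": ti, "condition": labels[ti],
                    "channel": ch, "start_s": win.start, "end_s": win.end,
                    "mean": F[ci, wi, ti, 0], "variance": F[ci, wi, ti, 1],
                    "skewness": F[ci, wi, ti, 2], "kurtosis": F[ci, wi, ti, 3],
                })
    return pd.DataFrame(rows)
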