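"""Trial epoching, stimulation/rest statistics, SNR and exclusion rules.

Each stimulation phase is paired with the immediately preceding rest phase
(the block design opens with rest, so every kept trial has a full baseline).
Per-trial stimulation-minus-rest means feed a classical paired t-test and an
SNR defined as mean / sample SD; sample SDs use the n-1 denominator
throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preproc import HemoSeries
from .synthgen import EventTable

logger = logging.getLogger(__name__)


@dataclass
class TrialEpoch:
    """One trial's rest (baseline) and stimulation segments for one channel."""

    trial: int
    condition: str
    channel: int               # 1-based
    rest: np.ndarray           # umol/l
    stim: np.ndarray
    sampling_rate: float
    chromophore: str = "o2hb"

    @property
    def baseline_mean(self) -> float:
        return float(self.rest.mean())

    @property
    def corrected_stim(self) -> np.ndarray:
        """Stimulation segment minus the baseline mean."""
        return self.stim - self.baseline_mean

    @property
    def stim_minus_rest(self) -> float:
        return float(self.stim.mean() - self.baseline_mean)


class PairedTTestResult(NamedTuple):
    t: float
    p: float
    df: int
    degenerate: bool = False


class SnrResult(NamedTuple):
    value: float
    defined: bool


def epoch(series: HemoSeries, events: EventTable | None = None,
          chromophore: str = "o2hb",
          rest_duration: float | None = None) -> list[TrialEpoch]:
    """Cut a continuous series into per-trial, per-channel epochs.

    The rest segment is the ``rest_duration`` seconds immediately preceding
    each stimulation onset (default: the time before the first onset, which
    is the block design's rest length).  Trials whose rest or stimulation
    segment would be truncated are dropped with a warning.
    """
    if events is None:
        events = series.events
    if events is None or events.n_trials == 0:
        raise ValueError("no event table available for epoching")
    fs = series.sampling_rate
    if rest_duration is None:
        rest_duration = float(events.onsets[0])
        if rest_duration <= 0:
            gaps = np.diff(events.onsets) - events.durations[:-1]
            rest_duration = float(gaps[0]) if len(gaps) else 0.0
    data = series.chromophore(chromophore)
    epochs: list[TrialEpoch] = []
    for k in range(events.n_trials):
        i_rest = int(round((events.onsets[k] - rest_duration) * fs))
        i_on = int(round(events.onsets[k] * fs))
        i_off = int(round((events.onsets[k] + events.durations[k]) * fs))
        if i_rest < 0 or i_on <= i_rest or i_off > series.n_samples:
            logger.warning("trial %d dropped: incomplete rest or stimulation block", k)
            continue
        for ch in range(series.n_channels):
            epochs.append(TrialEpoch(
                trial=k, condition=str(events.conditions[k]), channel=ch + 1,
                rest=data[ch, i_rest:i_on].copy(),
                stim=data[ch, i_on:i_off].copy(),
                sampling_rate=fs, chromophore=chromophore))
    return epochs


def paired_ttest(stim_means: Sequence[float], rest_means: Sequence[float]) -> PairedTTestResult:
    """Classical paired t-test (df = n-1, two-sided p).

    Zero-variance differences yield an explicit degenerate result
    (t = 0, p = 1, ``degenerate=True``) rather than a silent infinity.
    """
    stim = np.asarray(stim_means, dtype=float)
    rest = np.asarray(rest_means, dtype=float)
    if stim.shape != rest.shape:
        raise ValueError("stim and rest means must have equal length")
    n = len(stim)
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = stim - rest
    sd = d.std(ddof=1)
    if sd == 0:
        return PairedTTestResult(t=0.0, p=1.0, df=n - 1, degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return PairedTTestResult(t=float(t), p=float(p), df=n - 1)


def snr(values: Sequence[float]) -> SnrResult:
    """Ratio of the mean of ``values`` to their sample SD (n-1).

    Returns ``defined=False`` when the SD is zero.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("SNR needs n >= 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        return SnrResult(value=np.nan, defined=False)
    return SnrResult(value=float(v.mean() / sd), defined=True)


def snr_within_epoch(ep: TrialEpoch) -> SnrResult:
    """Alternative SNR reading: time-domain mean / SD inside one epoch."""
    return snr(ep.corrected_stim)


def stats_table(series: HemoSeries, events: EventTable | None = None) -> pd.DataFrame:
    """Per (channel, condition, chromophore) statistics of one recording.

    Columns: stimulation/rest means, paired t, p, df, SNR of the per-trial
    stim-rest differences, and trial count.
    """
    rows = []
    for chrom in ("o2hb", "hhb"):
        eps = epoch(series, events, chromophore=chrom)
        frame = pd.DataFrame({
            "channel": [e.channel for e in eps],
            "condition": [e.condition for e in eps],
            "stim_mean": [float(e.stim.mean()) for e in eps],
            "rest_mean": [e.baseline_mean for e in eps],
        })
        for (ch, cond), grp in frame.groupby(["channel", "condition"], sort=True):
            res = paired_ttest(grp.stim_mean.to_numpy(), grp.rest_mean.to_numpy())
            ratio = snr(grp.stim_mean.to_numpy() - grp.rest_mean.to_numpy())
            rows.append({
                "channel": ch, "condition": cond, "chromophore": chrom,
                "stim_mean": grp.stim_mean.mean(), "rest_mean": grp.rest_mean.mean(),
                "t": res.t, "p": res.p, "df": res.df, "degenerate": res.degenerate,
                "snr": ratio.value, "n_trials": len(grp),
            })
    return pd.DataFrame(rows)


@dataclass
class ExclusionResult:
    channel_excluded: dict          # channel (1-based) -> bool
    subject_excluded: bool
    reasons: list


def apply_exclusions(stats_by_run: Mapping[str, pd.DataFrame],
                     channel_alpha: float = 0.005,
                     subject_alpha: float = 0.05,
                     chromophore: str = "o2hb") -> ExclusionResult:
    """Channel and subject exclusion rules.

    A channel is excluded when no condition in any run shows a significant
    oxygenation change at ``channel_alpha``.  The subject is excluded when
    every channel in every supplied run (task and control) is non-significant
    at ``subject_alpha``.
    """
    if not stats_by_run:
        raise ValueError("no stats tables supplied")
    frames = []
    for run, df in stats_by_run.items():
        sel = df[df.chromophore == chromophore].copy()
        sel["run"] = run
        frames.append(sel)
    allstats = pd.concat(frames, ignore_index=True)

    reasons = []
    channel_excluded = {}
    for ch, grp in allstats.groupby("channel"):
        keep = bool((grp.p <= channel_alpha).any())
        channel_excluded[int(ch)] = not keep
        if not keep:
            reasons.append(f"channel {ch}: no significant change at alpha={channel_alpha}")

    subject_excluded = True
    for run, grp in allstats.groupby("run"):
        if (grp.p <= subject_alpha).any():
            subject_excluded = False
            break
    if subject_excluded:
        reasons.append(f"subject: all channels non-significant (p > {subject_alpha}) in all runs")
    return ExclusionResult(channel_excluded, subject_excluded, reasons)
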