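"""Group-level aggregation of per-subject search results.

Works either on freshly computed :class:`~nirstrial.flda_search.SearchResult`
objects or on the packaged transcription of the published per-subject result
table (``table2_results.csv``).  Also provides the Pearson feature/accuracy
correlation and the keystroke error-rate quotient.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FEATURE_NAMES
from .flda_search import SearchResult


def load_table2() -> pd.DataFrame:
    """Packaged per-subject best-combination table (channel, window, features,
    accuracy in percent)."""
    ref = resources.files("nirstrial.data") / "table2_results.csv"
    with ref.open("r") as fh:
        df = pd.read_csv(fh)
    df["features"] = df["features"].map(lambda s: tuple(s.split(";")))
    return df


def load_table1() -> pd.DataFrame:
    """Packaged per-channel amplitude/SNR table (umol/l; 'overall' rows are
    the across-channel summaries)."""
    ref = resources.files("nirstrial.data") / "table1_amplitudes.csv"
    with ref.open("r") as fh:
        return pd.read_csv(fh)


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (display convention of the result tables)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class GroupReport:
    n_subjects: int
    accuracy_mean_pct: float
    accuracy_sd_pct: float
    accuracy_min_pct: float
    accuracy_max_pct: float
    channel_counts: dict            # channel -> n subjects
    feature_counts: dict            # feature name -> n subjects
    interval_lengths: np.ndarray    # seconds per subject

    def rounded(self, ndigits: int = 1) -> dict:
        """Summary rounded to display precision (1 decimal for percents,
        half-up as in the published tables: 81.25 -> 81.3)."""
        return {
            "accuracy_mean_pct": round_half_up(self.accuracy_mean_pct, ndigits),
            "accuracy_sd_pct": round_half_up(self.accuracy_sd_pct, ndigits),
            "accuracy_min_pct": round_half_up(self.accuracy_min_pct, ndigits),
            "accuracy_max_pct": round_half_up(self.accuracy_max_pct, ndigits),
            "channel_counts": dict(self.channel_counts),
            "feature_counts": dict(self.feature_counts),
        }


def _normalize_records(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        df = results.copy()
        if "accuracy_pct" not in df:
            df["accuracy_pct"] = 100.0 * df["accuracy"]
        df["features"] = df["features"].map(
            lambda f: tuple(f.split(";")) if isinstance(f, str) else tuple(f))
        return df
    rows = []
    for i, r in enumerate(results, start=1):
        if isinstance(r, SearchResult):
            rows.append({"subject": i, "channel": r.best.channel,
                         "start_s": r.best.window.start,
                         "end_s": r.best.window.end,
                         "features": tuple(r.best.features),
                         "accuracy_pct": r.accuracy_pct})
        else:
            d = dict(r)
            d.setdefault("subject", i)
            d["features"] = tuple(d["features"])
            if "accuracy_pct" not in d:
                d["accuracy_pct"] = 100.0 * d["accuracy"]
            rows.append(d)
    return pd.DataFrame(rows)


def aggregate(results) -> GroupReport:
    """Summarise per-subject best combinations.

    Accepts a DataFrame (e.g. :func:`load_table2`), a list of
    :class:`SearchResult`, or a list of dicts with the same fields.
    """
    df = _normalize_records(results)
    if len(df) < 2:
        raise ValueError("need at least 2 subjects to aggregate")
    acc = df["accuracy_pct"].to_numpy(dtype=float)
    channel_counts = df["channel"].value_counts().to_dict()
    channel_counts = {int(k): int(v) for k, v in channel_counts.items()}
    feature_counts = {name: int(df["features"].map(lambda f: name in f).sum())
                      for name in FEATURE_NAMES}
    lengths = (df["end_s"] - df["start_s"]).to_numpy(dtype=float)
    return GroupReport(
        n_subjects=len(df),
        accuracy_mean_pct=float(acc.mean()),
        accuracy_sd_pct=float(acc.std(ddof=1)),
        accuracy_min_pct=float(acc.min()),
        accuracy_max_pct=float(acc.max()),
        channel_counts=channel_counts,
        feature_counts=feature_counts,
        interval_lengths=lengths,
    )


def feature_accuracy_correlation(feature_means: Sequence[float],
                                 accuracies: Sequence[float]) -> tuple:
    """Two-tailed Pearson correlation via the t-transform (df = n-2).

    By convention the inputs are restricted to subjects whose optimal set
    includes the feature.  Returns ``(r, p)``; zero variance in either vector
    yields ``(nan, nan)``.
    """
    x = np.asarray(feature_means, dtype=float)
    y = np.asarray(accuracies, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("correlation needs n >= 3")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        return (np.nan, np.nan)
    r = float(np.sum((x - x.mean()) * (y - y.mean())) / ((n - 1) * sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return (r, 0.0)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return (r, p)


def keystroke_error_rate(n_errors: int, n_taps: int) -> float:
    """(total number of errors) / (total number of finger taps)."""
    if n_taps <= 0:
        raise ValueError("n_taps must be positive")
    if not 0 <= n_errors <= n_taps:
        raise ValueError("n_errors must lie in [0, n_taps]")
    return n_errors / n_taps


def results_markdown(results) -> str:
    """Render per-subject results as a Markdown table."""
    df = _normalize_records(results)
    lines = ["| Subject | Channel | Time interval | Optimal feature set | Classification accuracy |",
             "|---|---|---|---|---|"]
    for _, row in df.iterrows():
        feats = ", ".join(row["features"])
        lines.append(f"| {row['subject']} | {row['channel']} | "
                     f"{row['start_s']}-{row['end_s']} s | {feats} | "
                     f"{row['accuracy_pct']:.1f}% |")
    rep = aggregate(df)
    lines.append(f"| **Overall** |  |  |  | "
                 f"**{rep.accuracy_mean_pct:.1f} ± {rep.accuracy_sd_pct:.1f}%** |")
    return "\n".join(lines)
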