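"""Fisher's linear discriminant, leave-one-out accuracy, and the exhaustive
channel x window x feature-subset search.

The discriminant is built from scratch: ``w = (S_w + ridge*I)^-1 (m_a - m_b)``
with ``S_w`` the summed within-class scatter and a midpoint threshold on the
projected class means (equal priors; the design is balanced).  Accuracy is
leave-one-out by default, so every reported accuracy is an exact multiple of
``1/n_trials``.

Ties in the search are broken toward the simplest model: fewer features,
then shorter window, then earlier start, then lower channel index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, AnalysisWindow, enumerate_windows

DEFAULT_RIDGE = 1e-8


@dataclass
class FldaModel:
    weights: np.ndarray
    threshold: float
    class_order: tuple           # (label on positive side, label on negative side)
    ridge: float

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.weights - self.threshold

    def predict(self, X: np.ndarray) -> np.ndarray:
        pos, neg = self.class_order
        return np.where(self.decision_values(X) > 0, pos, neg)


def flda_fit(class_a: np.ndarray, class_b: np.ndarray,
             ridge: float = DEFAULT_RIDGE, labels: tuple = ("a", "b")) -> FldaModel:
    """Fit Fisher's discriminant on two sample matrices (rows = samples)."""
    Xa = np.atleast_2d(np.asarray(class_a, dtype=float))
    Xb = np.atleast_2d(np.asarray(class_b, dtype=float))
    if Xa.ndim != 2 or Xb.ndim != 2 or Xa.shape[1] != Xb.shape[1]:
        raise ValueError("class matrices must be 2-D with equal dimensionality")
    if len(Xa) < 2 or len(Xb) < 2:
        raise ValueError("need at least 2 samples per class")
    ma, mb = Xa.mean(axis=0), Xb.mean(axis=0)
    Ca, Cb = Xa - ma, Xb - mb
    sw = Ca.T @ Ca + Cb.T @ Cb
    d = sw.shape[0]
    try:
        w = np.linalg.solve(sw + ridge * np.eye(d), ma - mb)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular within-class scatter; use a nonzero ridge") from err
    if ridge == 0 and not np.all(np.isfinite(w)):
        raise np.linalg.LinAlgError("singular within-class scatter; use a nonzero ridge")
    threshold = float(w @ (ma + mb) / 2.0)
    return FldaModel(weights=w, threshold=threshold, class_order=tuple(labels),
                     ridge=ridge)


def loocv_accuracy(X: np.ndarray, y: Sequence, ridge: float = DEFAULT_RIDGE) -> float:
    """Leave-one-out accuracy of the discriminant on labelled trials.

    Straightforward reference implementation: one :func:`flda_fit` per fold.
    The search uses an algebraically equivalent batched path
    (:func:`_loocv_batched`); their agreement is covered by tests.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=object)
    classes = _two_classes(y)
    for c in classes:
        if np.sum(y == c) < 2:
            raise ValueError("need at least 2 trials per class for LOOCV")
    correct = 0
    for i in range(len(y)):
        keep = np.ones(len(y), dtype=bool)
        keep[i] = False
        Xa = X[keep & (y == classes[0])]
        Xb = X[keep & (y == classes[1])]
        if len(Xa) == 0 or len(Xb) == 0:
            raise ValueError("a LOOCV fold has an empty class")
        model = flda_fit(Xa, Xb, ridge=ridge, labels=classes)
        if model.predict(X[i])[0] == y[i]:
            correct += 1
    return correct / len(y)


def _two_classes(y: np.ndarray) -> tuple:
    classes = sorted(set(y.tolist()), key=str)
    if len(classes) != 2:
        raise ValueError(f"expected exactly two classes, got {classes}")
    return tuple(classes)


def _loocv_batched(X: np.ndarray, mask_a: np.ndarray, ridge: float) -> np.ndarray:
    """Vectorised LOOCV accuracies for stacked feature sets.

    ``X`` has shape ``(..., n, d)`` where the leading axes index independent
    combinations sharing the same trial labels; ``mask_a`` marks class-a
    trials.  Returns accuracies of shape ``(...,)``.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape[-2], X.shape[-1]
    A = mask_a.astype(float)
    B = 1.0 - A
    na, nb = A.sum(), B.sum()
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 trials per class for LOOCV")

    sum_a = np.einsum("...nd,n->...d", X, A)
    sum_b = np.einsum("...nd,n->...d", X, B)
    gram_a = np.einsum("...nd,...ne,n->...de", X, X, A)
    gram_b = np.einsum("...nd,...ne,n->...de", X, X, B)

    na_i = na - A                      # (n,)
    nb_i = nb - B
    ma = (sum_a[..., None, :] - A[:, None] * X) / na_i[:, None]     # (..., n, d)
    mb = (sum_b[..., None, :] - B[:, None] * X) / nb_i[:, None]
    xxT = np.einsum("...nd,...ne->...nde", X, X)
    Ca = (gram_a[..., None, :, :] - A[:, None, None] * xxT
          - na_i[:, None, None] * np.einsum("...nd,...ne->...nde", ma, ma))
    Cb = (gram_b[..., None, :, :] - B[:, None, None] * xxT
          - nb_i[:, None, None] * np.einsum("...nd,...ne->...nde", mb, mb))
    sw = Ca + Cb + ridge * np.eye(d)
    w = np.linalg.solve(sw, (ma - mb)[..., None])[..., 0]           # (..., n, d)
    score = np.einsum("...nd,...nd->...n", X - (ma + mb) / 2.0, w)
    pred_a = score > 0
    correct = pred_a == mask_a
    return correct.mean(axis=-1)


@dataclass(frozen=True)
class CombinationSpec:
    """A candidate (channel, analysis window, feature subset)."""

    channel: int
    window: AnalysisWindow
    features: tuple

    def sort_key(self):
        return (len(self.features), self.window.length, self.window.start,
                self.channel, self.features)


@dataclass
class SearchResult:
    best: CombinationSpec
    accuracy: float                     # fraction in [0, 1]
    n_trials: int
    tie_set: list
    per_combination: pd.DataFrame = field(repr=False)

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.accuracy


def enumerate_subsets(n_features: int = len(FEATURE_NAMES)) -> list[tuple]:
    """All 2^n - 1 non-empty feature-index subsets, smallest first."""
    out = []
    for size in range(1, n_features + 1):
        out.extend(combinations(range(n_features), size))
    return out


def exhaustive_search(F: np.ndarray, labels: Sequence,
                      windows: Sequence[AnalysisWindow] | None = None,
                      channels: Sequence[int] | None = None,
                      ridge: float = DEFAULT_RIDGE) -> SearchResult:
    """Evaluate every (channel, window, feature subset) by LOOCV.

    ``F`` is the ``(n_channels, n_windows, n_trials, 4)`` grid from
    :func:`nirstrial.features.feature_matrix`.  Combinations with undefined
    (NaN) features in any trial are skipped.  Returns the argmax under the
    deterministic tie-breaking order together with the full accuracy table.
    """
    F = np.asarray(F, dtype=float)
    if windows is None:
        windows = enumerate_windows()
    if channels is None:
        channels = list(range(1, F.shape[0] + 1))
    if F.shape[:2] != (len(channels), len(windows)):
        raise ValueError("feature grid does not match channels/windows")
    y = np.asarray(labels, dtype=object)
    classes = _two_classes(y)
    mask_a = y == classes[0]
    n_trials = len(y)

    subsets = enumerate_subsets(F.shape[-1])
    acc = np.full((len(channels), len(windows), len(subsets)), np.nan)
    for ci in range(len(channels)):
        for si, subset in enumerate(subsets):
            Xs = F[ci][:, :, subset]                      # (n_windows, n, d)
            valid = ~np.isnan(Xs).any(axis=(1, 2))
            if not valid.any():
                continue
            acc[ci, valid, si] = _loocv_batched(Xs[valid], mask_a, ridge)

    if np.all(np.isnan(acc)):
        raise ValueError("every combination was rejected (undefined features)")
    best_acc = np.nanmax(acc)

    def make_spec(ci, wi, si):
        return CombinationSpec(channel=channels[ci], window=windows[wi],
                               features=tuple(FEATURE_NAMES[j] for j in subsets[si]))

    tie_idx = np.argwhere(np.isclose(acc, best_acc, rtol=0, atol=1e-12))
    tie_set = sorted((make_spec(*idx) for idx in tie_idx),
                     key=CombinationSpec.sort_key)

    rows = []
    for ci in range(len(channels)):
        for wi in range(len(windows)):
            for si in range(len(subsets)):
                rows.append((channels[ci], windows[wi].start, windows[wi].end,
                             ";".join(FEATURE_NAMES[j] for j in subsets[si]),
                             acc[ci, wi, si]))
    table = pd.DataFrame(rows, columns=["channel", "start_s", "end_s",
                                        "features", "accuracy"])
    return SearchResult(best=tie_set[0], accuracy=float(best_acc),
                        n_trials=n_trials, tie_set=tie_set,
                        per_combination=table)
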