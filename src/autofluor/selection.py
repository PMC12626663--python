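"""Entropy-based feature ranking and compact feature-set selection.

Features are ranked by information gain: the reduction in Shannon entropy of
the class labels achieved by the best binary threshold on the feature
(exhaustive search over midpoints between consecutive distinct sorted
values).  An equal-frequency multi-bin discretisation is available as an
alternative.  A greedy pass then admits features in rank order, skipping any
whose absolute Spearman correlation with an already-selected feature exceeds
``redundancy_rho``, until ``k`` features (default 8) are selected.

Ties in information gain are broken lexicographically by feature name so
runs are reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import spearmanr

from .errors import ValidationError
from .model import FeatureTable


def shannon_entropy(labels: Sequence) -> float:
    """Class-label entropy H = -sum p log2 p in bits, with 0*log(0) = 0."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValidationError("entropy of an empty label set is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _threshold_ig(values: np.ndarray, y: np.ndarray) -> float:
    """Best-threshold information gain; exhaustive over midpoints between
    consecutive distinct sorted values.  Vectorised over all splits."""
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    ys = y[order]
    # split points: after position i where v[i] < v[i+1]
    cut = np.nonzero(np.diff(v) > 0)[0]
    if cut.size == 0:
        return 0.0
    n = v.size
    n1 = float(y.sum())
    n0 = n - n1
    cum1 = np.cumsum(ys)[cut].astype(float)   # positives in left part
    nl = (cut + 1).astype(float)
    nr = n - nl
    cum0 = nl - cum1

    def h2(a, b):
        tot = a + b
        with np.errstate(divide="ignore", invalid="ignore"):
            pa = np.where(tot > 0, a / tot, 0.0)
            pb = np.where(tot > 0, b / tot, 0.0)
            out = -(np.where(pa > 0, pa * np.log2(pa), 0.0)
                    + np.where(pb > 0, pb * np.log2(pb), 0.0))
        return out

    h_y = h2(np.array([n0]), np.array([n1]))[0]
    cond = (nl / n) * h2(cum0, cum1) + (nr / n) * h2(n0 - cum0, n1 - cum1)
    return float(h_y - cond.min())


def _binned_ig(values: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    """Equal-frequency binning information gain."""
    edges = np.unique(np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1]))
    bins = np.searchsorted(edges, values, side="right")
    h_y = shannon_entropy(y)
    cond = 0.0
    n = values.size
    for b in np.unique(bins):
        sel = bins == b
        cond += sel.sum() / n * shannon_entropy(y[sel])
    return float(h_y - cond)


def information_gain(feature_values: Sequence[float], labels: Sequence,
                     discretization: str = "threshold",
                     n_bins: int = 10) -> float:
    """Information gain of one feature for a binary class variable, in bits.

    A constant feature has gain 0; gain never exceeds H(labels).
    """
    values = np.asarray(feature_values, dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError("feature values must be finite")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValidationError(f"information gain needs exactly 2 classes, got {classes.size}")
    y = (labels == classes[1]).astype(np.int64)
    if discretization == "threshold":
        return _threshold_ig(values, y)
    if discretization == "equal_frequency":
        return _binned_ig(values, y, n_bins)
    raise ValidationError(f"unknown discretization {discretization!r}")


@dataclass
class SelectionResult:
    """Ranked features and the selected compact subset for one comparison."""

    comparison: Tuple[str, str]
    ranked: List[Tuple[str, float]]      # (feature name, IG bits), nonincreasing
    selected: List[str]
    k: int
    redundancy_rho: float
    discretization: str
    truncated: bool = False              # fewer than k admissible features

    def to_dict(self) -> dict:
        return {
            "comparison": list(self.comparison),
            "selected": self.selected,
            "k": self.k,
            "redundancy_rho": self.redundancy_rho,
            "discretization": self.discretization,
            "truncated": self.truncated,
            "ranked": [[n, float(g)] for n, g in self.ranked],
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "SelectionResult":
        d = json.loads(Path(path).read_text())
        return cls(comparison=tuple(d["comparison"]),
                   ranked=[(n, float(g)) for n, g in d["ranked"]],
                   selected=list(d["selected"]), k=int(d["k"]),
                   redundancy_rho=float(d["redundancy_rho"]),
                   discretization=d["discretization"],
                   truncated=bool(d["truncated"]))


def rank_and_select(table: FeatureTable, class_a: str, class_b: str,
                    k: int = 8, redundancy_rho: float = 0.95,
                    discretization: str = "threshold",
                    n_bins: int = 10,
                    features: Optional[Sequence[str]] = None) -> SelectionResult:
    """Rank features by information gain for the ``class_a`` vs ``class_b``
    comparison and greedily select up to ``k`` non-redundant ones.

    Redundancy: a candidate is skipped if its absolute Spearman correlation
    with any already-selected feature exceeds ``redundancy_rho``.
    """
    present = set(table.data["group_label"].unique())
    if present != {class_a, class_b}:
        raise ValidationError(
            f"selection table must hold exactly the two compared classes "
            f"{{{class_a!r}, {class_b!r}}}; found {sorted(present)}"
        )
    sub = table
    names = list(features) if features is not None else list(table.feature_names)
    y = sub.labels
    gains = {
        name: information_gain(sub.data[name].to_numpy(dtype=float), y,
                               discretization=discretization, n_bins=n_bins)
        for name in names
    }
    ranked = sorted(gains.items(), key=lambda item: (-item[1], item[0]))

    cols = {name: sub.data[name].to_numpy(dtype=float) for name in names}
    selected: List[str] = []
    for name, _ in ranked:
        if len(selected) >= k:
            break
        redundant = False
        for s in selected:
            with warnings.catch_warnings():
                # constant columns have undefined rank correlation; treat
                # them as non-redundant (rho = 0)
                warnings.simplefilter("ignore")
                rho = spearmanr(cols[name], cols[s]).statistic
            if np.isnan(rho):
                rho = 0.0
            if abs(rho) > redundancy_rho:
                redundant = True
                break
        if not redundant:
            selected.append(name)
    return SelectionResult(
        comparison=(class_a, class_b),
        ranked=ranked,
        selected=selected,
        k=k,
        redundancy_rho=redundancy_rho,
        discretization=discretization,
        truncated=len(selected) < k,
    )
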