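"""mRMR feature ranking (MIQ scheme) and CHL-driven incremental feature selection.

Relevance and redundancy are both measured as mutual information (bits) of
empirically discretized variables. Continuous features are discretized by
equal-frequency binning (default 10 bins); binary and one-hot features
bypass binning. The MIQ quotient is

    score(f) = I(f; label) / mean_{s in selected} I(f; s)

with a small floor on the denominator because selected sets can contain
mutually independent (zero-MI) feature pairs.

Incremental feature selection (IFS) then evaluates each rank-ordered
prefix by cross-validated CHL and keeps the smallest prefix attaining the
curve's maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score

__all__ = [
    "RankedFeatures",
    "IFSCurve",
    "mutual_information",
    "mrmr_miq_rank",
    "ifs_select",
    "REDUNDANCY_FLOOR",
]

#: Floor on the mean-redundancy denominator of the MIQ quotient, in bits.
REDUNDANCY_FLOOR = 2.0 ** -20

_LN2 = math.log(2.0)


@dataclass
class RankedFeatures:
    """mRMR output: feature names in rank order with their MIQ components."""

    names: list
    relevance: dict  # feature -> MI(feature; label), bits
    redundancy: dict  # feature -> mean MI with previously selected, bits

    def __iter__(self):
        return iter(self.names)

    def __len__(self) -> int:
        return len(self.names)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, name in enumerate(self.names, start=1):
            rel = self.relevance[name]
            red = self.redundancy[name]
            rows.append(
                {
                    "rank": rank,
                    "feature": name,
                    "relevance": rel,
                    "redundancy": red,
                    "quotient": rel / max(red, REDUNDANCY_FLOOR),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class IFSCurve:
    """Cross-validated CHL per rank-prefix size; ``None`` marks a failed fit."""

    chl_by_size: dict

    def argmax(self) -> int:
        defined = {s: v for s, v in self.chl_by_size.items() if v is not None}
        if not defined:
            raise ValueError("IFS curve has no defined point")
        best = max(defined.values())
        return min(s for s, v in defined.items() if v == best)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": list(self.chl_by_size),
                "chl": [
                    (float("nan") if v is None else v)
                    for v in self.chl_by_size.values()
                ],
            }
        )


def _discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency binning; low-cardinality columns pass through."""
    x = np.asarray(x)
    distinct = np.unique(x)
    if distinct.size <= bins:
        # binary/one-hot/low-cardinality: already discrete
        return np.searchsorted(distinct, x)
    edges = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="left")


def mutual_information(x: Sequence, y: Sequence, bins: int = 10) -> float:
    """MI between a (possibly continuous) feature and labels, in bits.

    The feature is discretized by equal-frequency binning; MI is that of
    the joint empirical distribution, base-2 logarithm, hence >= 0 and
    bounded by min(H(x_binned), H(y)).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape[0] != y.shape[0] or x.shape[0] < 2:
        raise ValueError("x and y must have equal length >= 2")
    if np.unique(y).size < 2:
        raise ValueError("degenerate labels: y is constant")
    xb = _discretize(x, bins)
    return float(mutual_info_score(xb, y)) / _LN2


def mrmr_miq_rank(
    matrix: pd.DataFrame, labels: Sequence, bins: int = 10
) -> RankedFeatures:
    """Greedy mRMR ranking under the mutual-information-quotient scheme.

    The first feature maximizes relevance I(f; label); each subsequent
    feature maximizes relevance divided by its mean MI with the features
    already selected. Ties break lexicographically on the feature name, so
    the ranking is deterministic.
    """
    if matrix.shape[1] < 1:
        raise ValueError("empty feature matrix")
    labels = np.asarray(labels)
    names = list(matrix.columns)
    binned = {c: _discretize(matrix[c].to_numpy(), bins) for c in names}
    relevance = {
        c: float(mutual_info_score(binned[c], labels)) / _LN2 for c in names
    }

    pair_mi: dict = {}

    def mi_pair(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in pair_mi:
            pair_mi[key] = float(mutual_info_score(binned[a], binned[b])) / _LN2
        return pair_mi[key]

    selected: list = []
    redundancy: dict = {}
    remaining = set(names)
    while remaining:
        if not selected:
            # highest relevance; ties break to the lexicographically first name
            best = min(remaining, key=lambda c: (-relevance[c], c))
            redundancy[best] = 0.0
        else:
            def score(c: str) -> float:
                red = np.mean([mi_pair(c, s) for s in selected])
                return relevance[c] / max(red, REDUNDANCY_FLOOR)

            best = min(remaining, key=lambda c: (-score(c), c))
            redundancy[best] = float(
                np.mean([mi_pair(best, s) for s in selected])
            )
        selected.append(best)
        remaining.discard(best)
    return RankedFeatures(names=selected, relevance=relevance, redundancy=redundancy)


def ifs_select(
    matrix: pd.DataFrame,
    labels: Sequence,
    ranked: Sequence[str],
    trainer: Callable,
    k: int = 10,
    seed: int = 0,
    max_size: Optional[int] = None,
) -> tuple:
    """Incremental feature selection over rank-ordered prefixes.

    For each prefix size s, ``trainer(matrix[prefix], labels, k, seed)``
    must return a cross-validated :class:`~mirmeta.metrics.MetricPanel`;
    the prefix's score is its pooled CHL. A trainer failure (exception or
    undefined CHL) records ``None`` for that size and is excluded from the
    argmax. Returns the curve and the smallest best prefix.

    ``max_size`` caps the evaluated prefix length (default: all features).
    """
    ranked = list(ranked)
    if set(ranked) != set(matrix.columns):
        raise ValueError("ranked feature list must cover exactly the matrix's features")
    n = len(ranked) if max_size is None else min(max_size, len(ranked))
    curve: dict = {}
    for s in range(1, n + 1):
        prefix = ranked[:s]
        try:
            panel = trainer(matrix[prefix], labels, k, seed)
            curve[s] = panel.chl
        except Exception:
            curve[s] = None
    ifs_curve = IFSCurve(curve)
    best = ifs_curve.argmax()
    return ifs_curve, ranked[:best]
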