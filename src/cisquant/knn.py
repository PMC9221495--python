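"""Nearest-neighbor concentration assignment and leave-one-out evaluation.

A query tube is assigned the concentration label of its closest training
tube under the channel-averaged DTW distance (k = 1; larger k takes the mode
of the k nearest labels).  Quantification is thus classification onto the
training grid, not interpolation.  Ties — equal distances, or equal label
counts for k > 1 — are broken toward the smaller distance and then the lower
concentration, which keeps predictions deterministic regardless of input
order and errs on the conservative side for contamination screening.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .core import ColorTimeSeries
from .dtw import DTWConfig, distance_matrix, multichannel_distance
from .preprocess import PreprocessConfig, block_average


@dataclass(frozen=True)
class QuantifierConfig:
    """Neighbor count and tie-break rule; the study design uses k = 1."""

    k: int = 1
    tie_break: str = "smallest_distance_then_lowest_concentration"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.tie_break != "smallest_distance_then_lowest_concentration":
            raise ValueError(f"unknown tie_break {self.tie_break!r}")


@dataclass(frozen=True)
class Prediction:
    """One query's assigned concentration with its nearest-neighbor evidence.

    ``neighbor_ids`` / ``neighbor_distances`` list the k nearest training
    tubes in non-decreasing distance order.
    """

    tube_id: str
    true_concentration: float | None
    predicted_concentration: float
    neighbor_ids: tuple[str, ...]
    neighbor_distances: tuple[float, ...]

    def __post_init__(self) -> None:
        d = self.neighbor_distances
        if any(b < a for a, b in zip(d, d[1:])):
            raise ValueError("neighbor_distances must be non-decreasing")
        if any(x < 0 for x in d):
            raise ValueError("neighbor_distances must be non-negative")


def _assign(
    labels: list[float],
    tube_ids: list[str],
    distances: np.ndarray,
    qconfig: QuantifierConfig,
    query_id: str,
) -> Prediction:
    order = sorted(
        range(len(labels)), key=lambda i: (distances[i], labels[i], tube_ids[i])
    )
    k = qconfig.k
    nearest = order[:k]
    if k == 1:
        predicted = labels[nearest[0]]
    else:
        counts = Counter(labels[i] for i in nearest)
        top = max(counts.values())
        # mode; ties toward the label holding the smallest distance, then low
        tied = sorted(
            (c for c, n in counts.items() if n == top),
            key=lambda c: (min(distances[i] for i in nearest if labels[i] == c), c),
        )
        predicted = tied[0]
    return Prediction(
        tube_id=query_id,
        true_concentration=None,
        predicted_concentration=predicted,
        neighbor_ids=tuple(tube_ids[i] for i in nearest),
        neighbor_distances=tuple(float(distances[i]) for i in nearest),
    )


def predict(
    query: ColorTimeSeries,
    training: list[ColorTimeSeries],
    dconfig: DTWConfig | None = None,
    qconfig: QuantifierConfig | None = None,
) -> Prediction:
    """Assign the query a concentration from its k nearest training tubes."""
    dconfig = dconfig or DTWConfig()
    qconfig = qconfig or QuantifierConfig()
    if not training:
        raise ValueError("training set is empty")
    if qconfig.k > len(training):
        raise ValueError(
            f"k={qconfig.k} exceeds training-set size {len(training)}"
        )
    labels = []
    for s in training:
        if s.true_concentration is None:
            raise ValueError(f"training tube {s.tube_id!r} has no label")
        labels.append(float(s.true_concentration))
    dists = np.array(
        [multichannel_distance(query, s, dconfig) for s in training]
    )
    pred = _assign(labels, [s.tube_id for s in training], dists, qconfig,
                   query.tube_id)
    return Prediction(
        tube_id=query.tube_id,
        true_concentration=query.true_concentration,
        predicted_concentration=pred.predicted_concentration,
        neighbor_ids=pred.neighbor_ids,
        neighbor_distances=pred.neighbor_distances,
    )


def loo_evaluate(
    dataset: list[ColorTimeSeries],
    dconfig: DTWConfig | None = None,
    qconfig: QuantifierConfig | None = None,
    pconfig: PreprocessConfig | None = None,
) -> list[Prediction]:
    """Leave-one-out evaluation over a labeled dataset.

    Every series plays the query once against all the others.  Preprocessing
    (block averaging) is applied identically to every series up front, which
    is equivalent to per-fold application because the transform is
    per-series.  The full distance matrix is computed once and reused by
    every fold.
    """
    dconfig = dconfig or DTWConfig()
    qconfig = qconfig or QuantifierConfig()
    if len(dataset) < 2:
        raise ValueError("leave-one-out needs at least 2 series")
    if qconfig.k > len(dataset) - 1:
        raise ValueError(
            f"k={qconfig.k} exceeds LOO training-set size {len(dataset) - 1}"
        )
    for s in dataset:
        if s.true_concentration is None:
            raise ValueError(f"tube {s.tube_id!r} has no label; LOO needs labels")
    if pconfig is not None:
        dataset = [block_average(s, pconfig) for s in dataset]
    M = distance_matrix(dataset, dconfig)
    labels = [float(s.true_concentration) for s in dataset]
    ids = [s.tube_id for s in dataset]
    predictions: list[Prediction] = []
    for q in range(len(dataset)):
        rest = [i for i in range(len(dataset)) if i != q]
        pred = _assign(
            [labels[i] for i in rest],
            [ids[i] for i in rest],
            M[q, rest],
            qconfig,
            ids[q],
        )
        predictions.append(
            Prediction(
                tube_id=ids[q],
                true_concentration=labels[q],
                predicted_concentration=pred.predicted_concentration,
                neighbor_ids=pred.neighbor_ids,
                neighbor_distances=pred.neighbor_distances,
            )
        )
    return predictions
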