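"""Per-concentration summaries and error metrics for LOO predictions.

The summary mirrors the usual presentation of grid-quantification results:
for each true level, the mean and SD of the predicted concentrations, the
per-tube relative errors |predicted - true| / true, the rate of exact
assignments, and the count of "neighbor violations" — predictions landing
more than one position away from the truth on the sorted design grid.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .knn import Prediction


@dataclass(frozen=True)
class LevelSummary:
    """Statistics of the predictions whose true level is ``true_concentration``.

    ``sd_predicted`` is the sample SD (ddof=1), 0 for a single prediction.
    Relative errors are NaN at a true level of exactly 0 (no catalyst), where
    only the absolute errors are meaningful.
    """

    true_concentration: float
    n: int
    mean_predicted: float
    sd_predicted: float
    mean_relative_error: float
    max_relative_error: float
    mean_absolute_error: float
    max_absolute_error: float


@dataclass(frozen=True)
class EvaluationReport:
    per_level: tuple[LevelSummary, ...]
    overall_max_relative_error: float
    neighbor_violations: int
    exact_assignment_rate: float

    @property
    def n_predictions(self) -> int:
        return sum(lv.n for lv in self.per_level)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(lv) for lv in self.per_level])

    def to_json(self, path: "str | Path") -> None:
        payload = {
            "per_level": [asdict(lv) for lv in self.per_level],
            "overall_max_relative_error": self.overall_max_relative_error,
            "neighbor_violations": self.neighbor_violations,
            "exact_assignment_rate": self.exact_assignment_rate,
        }
        Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True))


def summarize(
    predictions: list[Prediction], level_grid: "list[float] | tuple[float, ...]"
) -> EvaluationReport:
    """Aggregate LOO predictions into an :class:`EvaluationReport`.

    Every prediction's true level must belong to ``level_grid``; the grid is
    sorted internally and neighbor violations are counted by index distance
    on it.
    """
    if not predictions:
        raise ValueError("no predictions to summarize")
    grid = sorted(float(c) for c in level_grid)
    index = {c: i for i, c in enumerate(grid)}
    by_level: dict[float, list[Prediction]] = {}
    violations = 0
    exact = 0
    for p in predictions:
        if p.true_concentration is None or float(p.true_concentration) not in index:
            raise ValueError(
                f"tube {p.tube_id!r}: true level {p.true_concentration!r} "
                f"not in the design grid"
            )
        t = float(p.true_concentration)
        q = float(p.predicted_concentration)
        if q not in index:
            raise ValueError(
                f"tube {p.tube_id!r}: predicted level {q!r} not in the grid"
            )
        by_level.setdefault(t, []).append(p)
        if abs(index[q] - index[t]) > 1:
            violations += 1
        if q == t:
            exact += 1

    levels: list[LevelSummary] = []
    for t in sorted(by_level):
        preds = np.array(
            [float(p.predicted_concentration) for p in by_level[t]]
        )
        abs_err = np.abs(preds - t)
        rel_err = abs_err / t if t > 0 else np.full_like(abs_err, math.nan)
        levels.append(
            LevelSummary(
                true_concentration=t,
                n=preds.size,
                mean_predicted=float(preds.mean()),
                sd_predicted=float(preds.std(ddof=1)) if preds.size > 1 else 0.0,
                mean_relative_error=float(np.mean(rel_err)),
                max_relative_error=float(np.max(rel_err)),
                mean_absolute_error=float(abs_err.mean()),
                max_absolute_error=float(abs_err.max()),
            )
        )
    finite_max = [
        lv.max_relative_error
        for lv in levels
        if not math.isnan(lv.max_relative_error)
    ]
    return EvaluationReport(
        per_level=tuple(levels),
        overall_max_relative_error=(max(finite_max) if finite_max else math.nan),
        neighbor_violations=violations,
        exact_assignment_rate=exact / len(predictions),
    )


def write_predictions_csv(
    predictions: list[Prediction], path: "str | Path"
) -> Path:
    """Export predictions: tube_id, true/predicted concentration, nearest
    neighbor(s) and distance(s)."""
    rows = [
        {
            "tube_id": p.tube_id,
            "true_concentration": p.true_concentration,
            "predicted_concentration": p.predicted_concentration,
            "nearest_neighbor": ";".join(p.neighbor_ids),
            "distance": ";".join(f"{d:.17g}" for d in p.neighbor_distances),
        }
        for p in predictions
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_predictions_csv(path: "str | Path") -> list[Prediction]:
    df = pd.read_csv(path)
    required = ["tube_id", "true_concentration", "predicted_concentration",
                "nearest_neighbor", "distance"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        Prediction(
            tube_id=str(r.tube_id),
            true_concentration=(
                None if pd.isna(r.true_concentration)
                else float(r.true_concentration)
            ),
            predicted_concentration=float(r.predicted_concentration),
            neighbor_ids=tuple(str(r.nearest_neighbor).split(";")),
            neighbor_distances=tuple(
                float(d) for d in str(r.distance).split(";")
            ),
        )
        for r in df.itertuples()
    ]


def plot_predictions(report: EvaluationReport, out: "str | Path") -> Path:
    """Mean predicted vs true concentration with SD bars and identity line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not report.per_level:
        raise ValueError("empty report")
    true = [lv.true_concentration for lv in report.per_level]
    mean = [lv.mean_predicted for lv in report.per_level]
    sd = [lv.sd_predicted for lv in report.per_level]
    fig, ax = plt.subplots(figsize=(5, 5))
    lims = [0, max(max(true), max(m + s for m, s in zip(mean, sd))) * 1.05]
    ax.plot(lims, lims, color="red", lw=1, label="ideal")
    ax.errorbar(true, mean, yerr=sd, fmt="o", color="tab:blue",
                capsize=3, label="predicted (mean ± SD)")
    ax.set_xlabel("true concentration")
    ax.set_ylabel("predicted concentration")
    ax.set_xlim(lims)
    ax.set_ylim(lims)
    ax.legend(loc="upper left", frameon=False)
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
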