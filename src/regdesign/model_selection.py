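"""Grid search over training-set size, hidden-layer width and random restarts.

Each grid cell draws a fresh seeded train/test split, trains one network,
and is evaluated by test-set SSE and mean absolute error plus train/test
Pearson correlations, all on the measurement (denormalized) scale. Cells
are named ``NET{size}_{hidden}_{restart}`` with 1-based restart indices;
the best cell is the one with the lowest test SSE (ties: highest test
correlation, then lexicographic name).
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np

from regdesign.ann import (
    TrainedModel,
    TrainingConfig,
    predict_strength,
    prediction_error,
    sse,
    train_network,
)
from regdesign.encoding import encode_library
from regdesign.library_io import StrengthLibrary

__all__ = [
    "GridCellResult",
    "GridSearchReport",
    "split_library",
    "pearson_r",
    "grid_cell_count",
    "grid_search",
    "select_best",
]


@dataclass
class GridCellResult:
    train_size: int
    hidden_neurons: int
    restart_index: int
    model_name: str
    sse_test: float
    error_test: float
    r_train: float
    r_test: float
    seed: int


@dataclass
class GridSearchReport:
    cells: list[GridCellResult]
    size_summary: dict[int, dict[str, float]] = field(default_factory=dict)

    @property
    def best(self) -> str:
        return select_best(self)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([vars(c) for c in self.cells])


def split_library(
    lib: StrengthLibrary, train_size: int, seed
) -> tuple[StrengthLibrary, StrengthLibrary]:
    """Uniformly random, disjoint, exhaustive train/test split.

    Reproducible by seed; ``2 <= train_size <= n - 1`` so the test set is
    never empty.
    """
    n = len(lib)
    if not 2 <= train_size <= n - 1:
        raise ValueError(
            f"train_size must lie in [2, {n - 1}] for a library of {n}, "
            f"got {train_size}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_idx = np.sort(order[:train_size])
    test_idx = np.sort(order[train_size:])
    return lib.subset(train_idx), lib.subset(test_idx)


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient.

    Raises for vectors shorter than 3 or with zero variance (undefined).
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("pearson_r needs at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson_r is undefined for a constant vector")
    xd = x - x.mean()
    yd = y - y.mean()
    r = float(np.dot(xd, yd) / math.sqrt(np.dot(xd, xd) * np.dot(yd, yd)))
    return max(-1.0, min(1.0, r))


def grid_cell_count(
    sizes: Sequence[int], hidden_range: Sequence[int], restarts: int
) -> int:
    """Planned number of grid cells, |sizes| * |hidden| * restarts (no training)."""
    sizes = list(sizes)
    hidden_range = list(hidden_range)
    if not sizes or not hidden_range or restarts < 1:
        raise ValueError("sizes and hidden_range must be non-empty, restarts >= 1")
    return len(sizes) * len(hidden_range) * restarts


def _cell_seed(master_seed: int, size: int, hidden: int, restart: int) -> int:
    """Deterministic per-cell seed so any cell is reproducible in isolation."""
    ss = np.random.SeedSequence([int(master_seed), size, hidden, restart])
    return int(ss.generate_state(1, dtype=np.uint64)[0])


def _evaluate_cell(
    lib: StrengthLibrary,
    size: int,
    hidden: int,
    restart: int,
    base_config: TrainingConfig,
    master_seed: int,
    return_model: bool = False,
):
    seed = _cell_seed(master_seed, size, hidden, restart)
    train_lib, test_lib = split_library(lib, size, seed)
    config = TrainingConfig(
        **{
            **vars(base_config),
            "hidden_neurons": hidden,
            "seed": (seed + 1) % 2**63,
        }
    )
    X_train = encode_library(train_lib.sequences())
    y_train = train_lib.strengths()
    model = train_network(X_train, y_train, config)
    pred_train = predict_strength(model, X_train)
    pred_test = predict_strength(model, encode_library(test_lib.sequences()))
    y_test = test_lib.strengths()
    cell = GridCellResult(
        train_size=size,
        hidden_neurons=hidden,
        restart_index=restart,
        model_name=f"NET{size}_{hidden}_{restart}",
        sse_test=sse(pred_test, y_test),
        error_test=prediction_error(pred_test, y_test),
        r_train=_safe_r(pred_train, y_train),
        r_test=_safe_r(pred_test, y_test),
        seed=seed,
    )
    if return_model:
        return cell, model
    return cell


def _safe_r(pred, target) -> float:
    try:
        return pearson_r(pred, target)
    except ValueError:
        return float("nan")


def grid_search(
    lib: StrengthLibrary,
    sizes: Sequence[int],
    hidden_range: Sequence[int],
    restarts: int,
    base_config: TrainingConfig | None = None,
    master_seed: int = 0,
) -> GridSearchReport:
    """Train and evaluate one model per (size, hidden, restart) triple.

    Child seeds derive deterministically from ``master_seed`` and the cell
    coordinates; restart indices are 1-based. The report carries per-size
    max/min test-SSE and test-error summaries.
    """
    sizes = sorted(set(int(s) for s in sizes))
    hidden_range = sorted(set(int(h) for h in hidden_range))
    if not sizes or not hidden_range or restarts < 1:
        raise ValueError("sizes and hidden_range must be non-empty, restarts >= 1")
    if max(sizes) > len(lib) - 1:
        raise ValueError(
            f"largest training size {max(sizes)} leaves no test set for a "
            f"library of {len(lib)}"
        )
    if base_config is None:
        base_config = TrainingConfig()
    cells = [
        _evaluate_cell(lib, size, hidden, restart, base_config, master_seed)
        for size in sizes
        for hidden in hidden_range
        for restart in range(1, restarts + 1)
    ]
    summary: dict[int, dict[str, float]] = {}
    for size in sizes:
        of_size = [c for c in cells if c.train_size == size]
        summary[size] = {
            "max_sse_test": max(c.sse_test for c in of_size),
            "min_sse_test": min(c.sse_test for c in of_size),
            "max_error_test": max(c.error_test for c in of_size),
            "min_error_test": min(c.error_test for c in of_size),
        }
    return GridSearchReport(cells=cells, size_summary=summary)


def select_best(report: GridSearchReport) -> str:
    """Name of the cell with minimum test SSE (ties: max r_test, then name)."""
    if not report.cells:
        raise ValueError("cannot select from an empty report")

    def key(c: GridCellResult):
        r = c.r_test if np.isfinite(c.r_test) else -2.0
        return (c.sse_test, -r, c.model_name)

    return min(report.cells, key=key).model_name


def retrain_cell(
    lib: StrengthLibrary,
    model_name: str,
    base_config: TrainingConfig | None = None,
    master_seed: int = 0,
) -> tuple[GridCellResult, TrainedModel]:
    """Reproduce a single grid cell (split + training) from its name."""
    if base_config is None:
        base_config = TrainingConfig()
    try:
        size, hidden, restart = map(int, model_name.removeprefix("NET").split("_"))
    except ValueError as exc:
        raise ValueError(f"malformed model name {model_name!r}") from exc
    return _evaluate_cell(
        lib, size, hidden, restart, base_config, master_seed, return_model=True
    )
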