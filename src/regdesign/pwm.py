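"""Position-weight-matrix baseline: log-odds scoring and log-activity fits.

The baseline scores a sequence as the sum of per-position log2 odds of its
bases versus a background distribution, then fits log-activity against the
score by ordinary least squares — the classical linear alternative the
network is compared to.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from regdesign.library_io import StrengthLibrary

__all__ = [
    "PWMModel",
    "build_pwm",
    "score_sequence",
    "score_library",
    "fit_log_activity",
    "FitResult",
    "best_log_activity_fit",
]

_BASES = "ACGT"
#: floor (bits) replacing -inf weights when a pseudocount of 0 is used
WEIGHT_FLOOR = -30.0


@dataclass
class PWMModel:
    """L x 4 log2-odds weights (columns in A, C, G, T order)."""

    weights: np.ndarray
    background: np.ndarray
    pseudocount: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        self.background = np.asarray(self.background, float)
        if self.weights.ndim != 2 or self.weights.shape[1] != 4:
            raise ValueError("weights must be an L x 4 matrix")

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    def to_frame(self):
        """Weights as a DataFrame with columns in A, G, C, T order."""
        import pandas as pd

        frame = pd.DataFrame(self.weights, columns=list(_BASES))
        return frame[["A", "G", "C", "T"]]


def build_pwm(
    seqs: Sequence[str],
    pseudocount: float = 0.5,
    background: Sequence[float] | None = None,
    seq_weights: Sequence[float] | None = None,
) -> PWMModel:
    """Estimate per-position log2-odds weights from an equal-length set.

    ``weights[i][b] = log2(freq(b, i) / background[b])`` with
    ``freq = (count + pseudocount) / (n + 4 * pseudocount)``. Counts may be
    weighted per sequence via ``seq_weights`` (e.g. by measured strength).
    A pseudocount of 0 is permitted; resulting ``-inf`` weights are floored
    at :data:`WEIGHT_FLOOR` bits.
    """
    seqs = [s.upper() for s in seqs]
    if len(seqs) < 2:
        raise ValueError("build_pwm needs at least 2 sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("all sequences must have equal length")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, float)
    if background.shape != (4,) or np.any(background <= 0) or not math.isclose(
        background.sum(), 1.0, abs_tol=1e-9
    ):
        raise ValueError("background must be 4 positive frequencies summing to 1")
    if seq_weights is None:
        w = np.ones(len(seqs))
    else:
        w = np.asarray(seq_weights, float)
        if w.size != len(seqs) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("seq_weights must be non-negative with positive sum")
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), L)
    counts = np.zeros((L, 4))
    for b_idx, base in enumerate(_BASES):
        counts[:, b_idx] = ((arr == base.encode()) * w[:, None]).sum(axis=0)
    total = w.sum()
    freq = (counts + pseudocount) / (total + 4 * pseudocount)
    with np.errstate(divide="ignore"):
        weights = np.log2(freq / background)
    weights = np.maximum(weights, WEIGHT_FLOOR)
    return PWMModel(weights=weights, background=background, pseudocount=pseudocount)


def score_sequence(pwm: PWMModel, seq: str) -> float:
    """Sum of per-position weight entries for the sequence's bases (bits)."""
    seq = seq.upper()
    if len(seq) != pwm.length:
        raise ValueError(
            f"sequence length {len(seq)} does not match PWM length {pwm.length}"
        )
    try:
        idx = [_BASES.index(b) for b in seq]
    except ValueError:
        bad = next(b for b in seq if b not in _BASES)
        raise ValueError(f"non-ACGT base {bad!r} in sequence") from None
    return float(pwm.weights[np.arange(pwm.length), idx].sum())


def score_library(pwm: PWMModel, seqs: Sequence[str]) -> np.ndarray:
    return np.array([score_sequence(pwm, s) for s in seqs])


@dataclass
class FitResult:
    slope: float
    intercept: float
    r: float
    subset: str | None = None


def fit_log_activity(
    scores, strengths, epsilon: float = 1e-3
) -> FitResult:
    """OLS fit of ``log2(strength + epsilon)`` against PWM score.

    Zero strengths are admissible thanks to the epsilon shift. Returns
    slope, intercept and the Pearson correlation of the fit.
    """
    scores = np.asarray(scores, float).ravel()
    strengths = np.asarray(strengths, float).ravel()
    if scores.size != strengths.size:
        raise ValueError("scores and strengths must have equal length")
    if scores.size < 3:
        raise ValueError("fit needs at least 3 points")
    if np.any(strengths < 0):
        raise ValueError("strengths must be >= 0")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if np.ptp(scores) == 0:
        raise ValueError("fit undefined for constant scores")
    y = np.log2(strengths + epsilon)
    slope, intercept = np.polyfit(scores, y, 1)
    if np.ptp(y) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(scores, y)[0, 1])
    return FitResult(slope=float(slope), intercept=float(intercept), r=r)


def best_log_activity_fit(
    lib: StrengthLibrary,
    pseudocount: float = 0.5,
    epsilon: float = 1e-3,
    high_threshold: float = 1.0,
) -> FitResult:
    """Best log-activity fit over three PWM training subsets.

    The PWM is built from (a) all sequences, (b) high-strength sequences
    (strength > ``high_threshold``), or (c) all sequences weighted by
    strength; all library members are then scored and fitted, and the fit
    with the largest |r| is returned with its subset label.
    """
    seqs = lib.sequences()
    strengths = lib.strengths()
    subsets: dict[str, tuple[list[str], np.ndarray | None]] = {
        "all": (seqs, None),
    }
    high = [s for s, y in zip(seqs, strengths) if y > high_threshold]
    if len(high) >= 2:
        subsets["high"] = (high, None)
    if np.sum(strengths) > 0:
        subsets["weighted"] = (seqs, strengths)
    best: FitResult | None = None
    for label, (train_seqs, weights) in subsets.items():
        pwm = build_pwm(train_seqs, pseudocount=pseudocount, seq_weights=weights)
        scores = score_library(pwm, seqs)
        if np.ptp(scores) == 0:
            continue
        fit = fit_log_activity(scores, strengths, epsilon=epsilon)
        fit.subset = label
        if best is None or abs(fit.r) > abs(best.r):
            best = fit
    if best is None:
        raise ValueError("no subset produced a non-degenerate fit")
    return best
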