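"""In-silico mutation scanning, key-point analysis and de-novo sequence design.

The trained network is used as an oracle: every single-base substitution of
the wild-type element is scored (3 alternatives per site), substitutions
changing the predicted strength by at least 20% relative to the wild-type
prediction are classified as positive/negative key points, and new elements
with a desired strength are obtained either by screening a randomly
mutagenized in-silico library or by searching combinations of key-point
mutations.
"""

from __future__ import annotations

import itertools
from collections import Counter
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from regdesign.ann import TrainedModel, predict_strength
from regdesign.encoding import encode_library

__all__ = [
    "MutationEffect",
    "KeyPointSet",
    "DesignCandidate",
    "DesignResult",
    "point_scan",
    "classify_key_points",
    "generate_insilico_library",
    "design_by_library",
    "design_by_keypoints",
    "conservation_profile",
    "mutation_type_counts",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class MutationEffect:
    """Predicted effect of one single-base substitution (1-based position)."""

    position: int
    from_base: str
    to_base: str
    predicted_strength: float
    delta_relative: float

    def __post_init__(self) -> None:
        if self.from_base == self.to_base:
            raise ValueError("from_base and to_base must differ")


@dataclass
class KeyPointSet:
    """Substitutions whose predicted relative effect clears +/- threshold."""

    positive_points: list[MutationEffect]
    negative_points: list[MutationEffect]
    threshold: float = 0.20

    def __post_init__(self) -> None:
        for eff in self.positive_points:
            if eff.delta_relative < self.threshold:
                raise ValueError(
                    f"positive point at {eff.position} below threshold"
                )
        for eff in self.negative_points:
            if eff.delta_relative > -self.threshold:
                raise ValueError(
                    f"negative point at {eff.position} above -threshold"
                )

    def __len__(self) -> int:
        return len(self.positive_points) + len(self.negative_points)

    def all_points(self) -> list[MutationEffect]:
        return list(self.positive_points) + list(self.negative_points)


@dataclass
class DesignCandidate:
    sequence: str
    predicted_strength: float
    mutations: list[tuple[int, str, str]]  # (position, from, to)


@dataclass
class DesignResult:
    candidates: list[DesignCandidate]
    desired_strength: float
    tolerance: float
    approach: str  # "library" | "keypoint"
    satisfied: bool = True
    nearest_achieved: float | None = None


def point_scan(model: TrainedModel, wt_seq: str) -> list[MutationEffect]:
    """Score every single-base substitution of the wild type (3 per site).

    Returns exactly ``3 * L`` effects ordered by position then alternative
    base (ACGT order). ``delta_relative`` is computed against the model's
    own wild-type prediction.
    """
    wt_seq = wt_seq.upper()
    L = model.sequence_length
    if len(wt_seq) != L:
        raise ValueError(
            f"wild-type length {len(wt_seq)} does not match model length {L}"
        )
    variants: list[tuple[int, str, str]] = []
    seqs: list[str] = []
    for pos in range(L):
        wt_base = wt_seq[pos]
        for alt in _BASES:
            if alt == wt_base:
                continue
            variants.append((pos + 1, wt_base, alt))
            seqs.append(wt_seq[:pos] + alt + wt_seq[pos + 1 :])
    preds = predict_strength(model, encode_library(seqs))
    wt_pred = float(predict_strength(model, wt_seq)[0])
    return [
        MutationEffect(
            position=pos,
            from_base=fb,
            to_base=tb,
            predicted_strength=float(p),
            delta_relative=float((p - wt_pred) / wt_pred),
        )
        for (pos, fb, tb), p in zip(variants, preds)
    ]


def classify_key_points(
    effects: Sequence[MutationEffect],
    wt_predicted: float,
    threshold: float = 0.20,
) -> KeyPointSet:
    """Partition scan effects at +/- ``threshold`` relative change (inclusive).

    Effects inside the band are discarded. ``wt_predicted`` must be
    positive — relative change against a non-positive baseline is
    undefined.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if wt_predicted <= 0:
        raise ValueError("relative change undefined for wt_predicted <= 0")
    positive = [e for e in effects if e.delta_relative >= threshold]
    negative = [e for e in effects if e.delta_relative <= -threshold]
    return KeyPointSet(
        positive_points=positive, negative_points=negative, threshold=threshold
    )


def generate_insilico_library(
    wt_seq: str, n: int, mutation_rate: float, seed
) -> list[str]:
    """Random mutants of the wild type, i.i.d. per-base substitution.

    Each base mutates independently with probability ``mutation_rate``,
    uniformly over the 3 alternative bases. Duplicates are permitted;
    reproducible by seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < mutation_rate < 1:
        raise ValueError("mutation_rate must lie in (0, 1)")
    wt_seq = wt_seq.upper()
    L = len(wt_seq)
    rng = np.random.default_rng(seed)
    wt_arr = np.frombuffer(wt_seq.encode(), dtype="S1")
    base_arr = np.frombuffer(_BASES.encode(), dtype="S1")
    # per base: 3 alternatives, excluding the wild-type base
    alt_table = np.array(
        [[b for b in range(4) if _BASES[b] != chr(c[0])] for c in wt_arr]
    )  # L x 3
    out: list[str] = []
    for _ in range(n):
        mutate = rng.random(L) < mutation_rate
        picks = rng.integers(0, 3, size=L)
        chars = wt_arr.copy()
        idx = np.nonzero(mutate)[0]
        chars[idx] = base_arr[alt_table[idx, picks[idx]]]
        out.append(chars.tobytes().decode())
    return out


def _mutations_vs_wt(wt_seq: str, seq: str) -> list[tuple[int, str, str]]:
    return [
        (i + 1, a, b) for i, (a, b) in enumerate(zip(wt_seq, seq)) if a != b
    ]


def design_by_library(
    model: TrainedModel,
    wt_seq: str,
    desired: float,
    tolerance: float,
    n: int = 10000,
    mutation_rate: float = 0.20,
    seed=0,
    k: int = 10,
    include_wild_type: bool = True,
) -> DesignResult:
    """Design by screening a random in-silico library (approach i).

    Generates ``n`` random mutants, scores them all with the model, and
    returns the ``k`` sequences whose predictions are closest to
    ``desired``. The result is flagged unsatisfied (never an exception)
    when no candidate lands within ``tolerance``.

    Raises
    ------
    ValueError
        If ``desired`` exceeds the model's normalization maximum — the
        network cannot predict strengths beyond the strongest training
        example, so such designs are out of reach by construction.
    """
    wt_seq = wt_seq.upper()
    if desired < 0:
        raise ValueError("desired strength must be >= 0")
    if desired > model.normalization_max:
        raise ValueError(
            f"cannot design strength {desired}: the model is bounded by the "
            f"maximum training strength {model.normalization_max}"
        )
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    pool = generate_insilico_library(wt_seq, n, mutation_rate, seed)
    if include_wild_type:
        pool.append(wt_seq)
    preds = predict_strength(model, encode_library(pool))
    order = sorted(
        range(len(pool)), key=lambda i: (abs(preds[i] - desired), pool[i])
    )
    top = order[: max(k, 1)]
    candidates = [
        DesignCandidate(
            sequence=pool[i],
            predicted_strength=float(preds[i]),
            mutations=_mutations_vs_wt(wt_seq, pool[i]),
        )
        for i in top
    ]
    nearest = candidates[0].predicted_strength
    satisfied = abs(nearest - desired) <= tolerance
    if satisfied:
        candidates = [
            c
            for c in candidates
            if abs(c.predicted_strength - desired) <= tolerance
        ]
    return DesignResult(
        candidates=candidates,
        desired_strength=desired,
        tolerance=tolerance,
        approach="library",
        satisfied=satisfied,
        nearest_achieved=nearest,
    )


def _apply_mutations(wt_seq: str, muts) -> str:
    chars = list(wt_seq)
    for eff in muts:
        chars[eff.position - 1] = eff.to_base
    return "".join(chars)


def _score_combos(model, wt_seq, combos):
    seqs = [_apply_mutations(wt_seq, c) for c in combos]
    return seqs, predict_strength(model, encode_library(seqs))


def design_by_keypoints(
    model: TrainedModel,
    wt_seq: str,
    keypoints: KeyPointSet,
    desired: float,
    tolerance: float,
    max_mutations: int = 5,
    beam_width: int = 50,
    k: int = 10,
    search: str = "auto",
) -> DesignResult:
    """Design by combining key-point mutations (approach ii).

    Searches subsets of the key-point substitutions (at most one per
    position, at most ``max_mutations`` total) for combinations whose
    predicted strength is nearest ``desired``. With 10 or fewer key points
    the search is exhaustive; otherwise a beam search of width
    ``beam_width`` grows combinations one mutation at a time. Deterministic
    given its inputs; an empty-tolerance miss is reported as an unsatisfied
    result, not an exception.

    ``search`` selects the strategy: ``"auto"`` (exhaustive when <= 10 key
    points, beam otherwise), ``"exhaustive"``, or ``"beam"``.
    """
    wt_seq = wt_seq.upper()
    points = keypoints.all_points()
    if not points:
        raise ValueError("keypoints must be non-empty")
    if max_mutations < 1:
        raise ValueError("max_mutations must be >= 1")
    if beam_width < 1:
        raise ValueError("beam_width must be >= 1")
    # stable deterministic order
    points = sorted(points, key=lambda e: (e.position, e.to_base))

    if search not in ("auto", "exhaustive", "beam"):
        raise ValueError(f"unknown search strategy {search!r}")
    if search == "auto":
        search = "exhaustive" if len(points) <= 10 else "beam"
    if search == "exhaustive":
        combos = _enumerate_combos(points, max_mutations)
    else:
        combos = _beam_combos(model, wt_seq, points, desired, max_mutations,
                              beam_width)
    combos = [()] + [c for c in combos if c]  # wild type is the empty combo
    seqs, preds = _score_combos(model, wt_seq, combos)
    order = sorted(
        range(len(combos)), key=lambda i: (abs(preds[i] - desired), seqs[i])
    )
    top = order[: max(k, 1)]
    candidates = [
        DesignCandidate(
            sequence=seqs[i],
            predicted_strength=float(preds[i]),
            mutations=[(e.position, e.from_base, e.to_base) for e in combos[i]],
        )
        for i in top
    ]
    nearest = candidates[0].predicted_strength
    satisfied = abs(nearest - desired) <= tolerance
    if satisfied:
        candidates = [
            c
            for c in candidates
            if abs(c.predicted_strength - desired) <= tolerance
        ]
    return DesignResult(
        candidates=candidates,
        desired_strength=desired,
        tolerance=tolerance,
        approach="keypoint",
        satisfied=satisfied,
        nearest_achieved=nearest,
    )


def _enumerate_combos(points, max_mutations):
    """All subsets with <= 1 mutation per position and <= max_mutations total."""
    combos = []
    for r in range(1, min(max_mutations, len(points)) + 1):
        for combo in itertools.combinations(points, r):
            positions = [e.position for e in combo]
            if len(set(positions)) == len(positions):
                combos.append(combo)
    return combos


def _beam_combos(model, wt_seq, points, desired, max_mutations, beam_width):
    seen: set[frozenset] = set()
    beam: list[tuple] = [()]
    collected: list[tuple] = []
    for _ in range(max_mutations):
        expansions = []
        for combo in beam:
            used = {e.position for e in combo}
            last = max((points.index(e) for e in combo), default=-1)
            for j in range(last + 1, len(points)):
                e = points[j]
                if e.position in used:
                    continue
                new = combo + (e,)
                key = frozenset(new)
                if key not in seen:
                    seen.add(key)
                    expansions.append(new)
        if not expansions:
            break
        _, preds = _score_combos(model, wt_seq, expansions)
        ranked = sorted(
            range(len(expansions)),
            key=lambda i: (
                abs(preds[i] - desired),
                tuple((e.position, e.to_base) for e in expansions[i]),
            ),
        )
        beam = [expansions[i] for i in ranked[:beam_width]]
        collected.extend(beam)
    return collected


def conservation_profile(seqs: Sequence[str]) -> np.ndarray:
    """Per-position information content (bits) of an equal-length alignment.

    ``2 - H(p)`` per column, with ``H`` the Shannon entropy of the observed
    base frequencies (raw frequencies, no small-sample correction). A fully
    conserved column scores 2 bits, a uniform column 0 bits.
    """
    seqs = [s.upper() for s in seqs]
    if len(seqs) < 2:
        raise ValueError("conservation_profile needs at least 2 sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("all sequences must have equal length")
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), L)
    profile = np.empty(L)
    for j in range(L):
        counts = np.array([np.sum(arr[:, j] == b.encode()) for b in _BASES], float)
        if counts.sum() != len(seqs):
            raise ValueError(f"non-ACGT character in column {j + 1}")
        p = counts / counts.sum()
        nz = p[p > 0]
        profile[j] = 2.0 + float(np.sum(nz * np.log2(nz)))
    return profile


def mutation_type_counts(keypoints: KeyPointSet) -> dict:
    """Tally key-point substitutions per (from, to) pair and per AT<->GC class.

    Returns a dict with per-class Counters keyed ``"A>G"`` style plus the
    aggregated weak-to-strong (``AT->GC``) and strong-to-weak (``GC->AT``)
    counts, split by positive/negative key points.
    """
    result: dict = {}
    for label, points in (
        ("positive", keypoints.positive_points),
        ("negative", keypoints.negative_points),
    ):
        pairs = Counter(f"{e.from_base}>{e.to_base}" for e in points)
        at_to_gc = sum(
            1 for e in points if e.from_base in "AT" and e.to_base in "GC"
        )
        gc_to_at = sum(
            1 for e in points if e.from_base in "GC" and e.to_base in "AT"
        )
        result[label] = {
            "pairs": dict(pairs),
            "AT_to_GC": at_to_gc,
            "GC_to_AT": gc_to_at,
            "total": len(points),
        }
    result["total"] = len(keypoints)
    return result
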