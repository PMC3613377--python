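"""Synthetic mutant libraries with a planted sequence-to-strength ground truth.

The real 100-member mutant library is not machine-readable, so this module
emulates it: a fixed 224-nt wild type, per-(position, base) additive latent
effects pushed through a saturating logistic nonlinearity scaled so the
wild type maps to exactly 1 and all strengths stay inside [0, s_max]
(default 3.559). A requested number of strong positive and negative key
sites is planted (the rest carry mild effects), Gaussian measurement noise
is added, and libraries are assembled by screening a large mutant pool for
a strength distribution with the desired positive fraction — mirroring how
the original library was picked from thousands of screened clones.

Everything is deterministic given its seeds, and the planted map is exposed
so downstream modules can be scored on how well they recover it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from regdesign.library_io import SequenceRecord, StrengthLibrary

__all__ = [
    "GroundTruth",
    "make_ground_truth",
    "generate_library",
    "save_ground_truth",
    "load_ground_truth",
    "DEFAULT_WT_SEQ",
]

_BASES = "ACGT"

#: Packaged 224-nt wild-type fixture (any user sequence may replace it).
DEFAULT_WT_SEQ = (
    "GCGAGGTGTCAGATCACTTATAACGGCCATAGTCTCGCCCCCTCCGAAACTGGTGACGTACGTCCACGCG"
    "GCACTCAGATTGTTTAACGTCATCACCCGGGCGCGAGAGGGCAGATAGTTTACGACATGCGGGTGGAAAG"
    "CCTATCTGTGCTCCTTGCATTTGCCCCTTAATCTTCCATGGCTCCCCGACACTAACTTGCATGCAGCAAA"
    "TACTTACTACCGCC"
)


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, float)))


@dataclass
class GroundTruth:
    """Planted sequence-to-strength map.

    ``site_effects[(position, base)]`` is the additive latent-score effect
    of substituting ``base`` at 1-based ``position``; the wild type has
    score 0 and strength exactly 1. Strength of any sequence is
    ``s_max * sigmoid(score + logit(1 / s_max))``.
    """

    wt_seq: str
    site_effects: dict[tuple[int, str], float]
    noise_sd: float
    s_max: float
    seed: int
    planted_positive: list[tuple[int, str]] = field(default_factory=list)
    planted_negative: list[tuple[int, str]] = field(default_factory=list)

    @property
    def offset(self) -> float:
        """Logit offset placing the wild type at strength exactly 1."""
        return _logit(1.0 / self.s_max)

    def latent_score(self, seq: str) -> float:
        seq = seq.upper()
        if len(seq) != len(self.wt_seq):
            raise ValueError(
                f"sequence length {len(seq)} != wild-type length {len(self.wt_seq)}"
            )
        return float(
            sum(
                self.site_effects[(i + 1, b)]
                for i, (b, wt) in enumerate(zip(seq, self.wt_seq))
                if b != wt
            )
        )

    def strength(self, seq: str) -> float:
        """Noise-free ground-truth strength of a sequence, in (0, s_max)."""
        return float(self.s_max * _sigmoid(self.latent_score(seq) + self.offset))

    def relative_effect(self, position: int, base: str) -> float:
        """True single-substitution relative strength change vs the wild type."""
        e = self.site_effects[(position, base)]
        return float(self.s_max * _sigmoid(e + self.offset) - 1.0)

    def planted_key_sites(self, min_effect: float = 0.3) -> dict[str, list]:
        """Planted (position, base) pairs whose true |relative effect| >= min_effect."""
        pos = [
            pb for pb in self.planted_positive
            if self.relative_effect(*pb) >= min_effect
        ]
        neg = [
            pb for pb in self.planted_negative
            if self.relative_effect(*pb) <= -min_effect
        ]
        return {"positive": pos, "negative": neg}


def make_ground_truth(
    seed: int,
    L: int = 224,
    n_positive_sites: int = 15,
    n_negative_sites: int = 120,
    noise_sd: float = 0.05,
    s_max: float = 3.559,
    wt_seq: str | None = None,
    positive_effect_range: tuple[float, float] = (0.6, 1.8),
    negative_effect_range: tuple[float, float] = (-0.9, -0.5),
    mild_effect_sd: float = 0.04,
) -> GroundTruth:
    """Build a planted ground truth with the requested key-site counts.

    Positive/negative planted sites get true relative effects drawn
    uniformly from the given ranges (defaults keep them clear of the 20%
    classification threshold); every other (position, base) substitution
    gets a mild effect (relative change of a few percent). Deterministic
    by seed.
    """
    if wt_seq is None:
        if L == len(DEFAULT_WT_SEQ):
            wt_seq = DEFAULT_WT_SEQ
        else:
            rng_wt = np.random.default_rng(seed + 777)
            wt_seq = "".join(rng_wt.choice(list(_BASES), L))
    wt_seq = wt_seq.upper()
    if len(wt_seq) != L:
        raise ValueError(f"wt_seq length {len(wt_seq)} != L = {L}")
    if s_max <= 1:
        raise ValueError("s_max must exceed 1 (wild type is 1)")
    all_sites = [
        (i + 1, b) for i in range(L) for b in _BASES if b != wt_seq[i]
    ]
    if n_positive_sites + n_negative_sites > len(all_sites):
        raise ValueError(
            f"requested {n_positive_sites + n_negative_sites} planted sites, "
            f"but only {len(all_sites)} substitutions exist"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(all_sites), n_positive_sites + n_negative_sites,
                        replace=False)
    positive = [all_sites[i] for i in chosen[:n_positive_sites]]
    negative = [all_sites[i] for i in chosen[n_positive_sites:]]

    offset = _logit(1.0 / s_max)

    def effect_for_relative(r: float) -> float:
        # invert strength(e) = s_max * sigmoid(e + offset) = 1 + r
        target = (1.0 + r) / s_max
        return _logit(target) - offset

    site_effects: dict[tuple[int, str], float] = {}
    for pb in all_sites:
        r = float(np.clip(rng.normal(0.0, mild_effect_sd), -0.15, 0.15))
        site_effects[pb] = effect_for_relative(r)
    lo, hi = positive_effect_range
    if not 0 < lo < hi:
        raise ValueError("positive_effect_range must be increasing and positive")
    if hi >= s_max - 1:
        raise ValueError("positive effects cannot push strength beyond s_max")
    for pb in positive:
        site_effects[pb] = effect_for_relative(float(rng.uniform(lo, hi)))
    lo, hi = negative_effect_range
    if not -1 < lo < hi < 0:
        raise ValueError("negative_effect_range must be increasing within (-1, 0)")
    for pb in negative:
        site_effects[pb] = effect_for_relative(float(rng.uniform(lo, hi)))
    return GroundTruth(
        wt_seq=wt_seq,
        site_effects=site_effects,
        noise_sd=noise_sd,
        s_max=s_max,
        seed=int(seed),
        planted_positive=positive,
        planted_negative=negative,
    )


def _mutate_pool(gt: GroundTruth, pool_size: int, mutation_rate: float, rng):
    """Mutant pool with heterogeneous per-sequence rates averaging the target.

    Per-clone mutational load varies widely in an error-prone library; the
    per-sequence rate is drawn uniformly in (0.1, 1.9) x mutation_rate so
    the pool mean matches ``mutation_rate`` while covering light and heavy
    mutants.
    """
    L = len(gt.wt_seq)
    wt_arr = np.frombuffer(gt.wt_seq.encode(), dtype="S1")
    base_arr = np.frombuffer(_BASES.encode(), dtype="S1")
    alt_table = np.array(
        [[b for b in range(4) if _BASES[b] != chr(c[0])] for c in wt_arr]
    )
    seqs = []
    rates = mutation_rate * rng.uniform(0.1, 1.9, size=pool_size)
    for i in range(pool_size):
        mutate = rng.random(L) < rates[i]
        picks = rng.integers(0, 3, size=L)
        chars = wt_arr.copy()
        idx = np.nonzero(mutate)[0]
        chars[idx] = base_arr[alt_table[idx, picks[idx]]]
        seqs.append(chars.tobytes().decode())
    return seqs


def generate_library(
    gt: GroundTruth,
    n: int = 100,
    mutation_rate: float = 0.20,
    seed: int = 0,
    positive_fraction_target: float = 0.20,
    wild_type_id: str = "WT",
    pool_factor: int = 40,
) -> StrengthLibrary:
    """Assemble a measured library of ``n`` records including the wild type.

    A large mutant pool (``pool_factor * n`` clones) is generated and
    noisy strengths are measured for all of them; the library then keeps
    the wild type (strength exactly 1) plus mutants picked to spread
    strengths evenly while hitting the requested positive fraction
    (strength > 1) within +/-0.05 when the pool allows it. If the pool
    cannot supply enough positives the best effort is returned and the
    library's ``warning_flags`` records the shortfall.
    """
    if n < 2:
        raise ValueError("library size must be >= 2")
    if not 0 < mutation_rate < 1:
        raise ValueError("mutation_rate must lie in (0, 1)")
    if not 0 <= positive_fraction_target < 1:
        raise ValueError("positive_fraction_target must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    pool = _mutate_pool(gt, max(pool_factor * n, 500), mutation_rate, rng)
    truth = np.array([gt.strength(s) for s in pool])
    noisy = np.clip(
        truth + rng.normal(0.0, gt.noise_sd, size=len(pool)), 0.0, gt.s_max
    )

    n_mutants = n - 1
    want_pos = int(round(positive_fraction_target * n))
    pos_idx = np.nonzero(noisy > 1.0)[0]
    neg_idx = np.nonzero(noisy <= 1.0)[0]
    warnings_list: list[str] = []
    take_pos = min(want_pos, len(pos_idx), n_mutants)
    if take_pos < want_pos:
        warnings_list.append(
            f"only {take_pos} positive mutants available in the pool "
            f"(wanted {want_pos})"
        )
    take_neg = n_mutants - take_pos
    if take_neg > len(neg_idx):  # pragma: no cover - pathological pool
        raise ValueError("pool too small to assemble the requested library")

    def spread(indices: np.ndarray, k: int, skew: float = 1.0) -> list[int]:
        """k indices whose strengths spread over the available range.

        Picks the nearest unused pool member to each of k spaced target
        strengths, emulating screening a large pool for a strength
        gradient. ``skew`` > 1 biases the targets toward the low end, as
        in a mutant pool where most clones are heavily impaired.
        """
        if k == 0:
            return []
        vals = noisy[indices]
        grid = np.linspace(0.0, 1.0, k) ** skew
        targets = vals.min() + (vals.max() - vals.min()) * grid
        chosen: list[int] = []
        used = np.zeros(len(indices), dtype=bool)
        for t in targets:
            gaps = np.where(used, np.inf, np.abs(vals - t))
            j = int(np.argmin(gaps))
            used[j] = True
            chosen.append(int(indices[j]))
        return chosen

    selected = spread(pos_idx, take_pos) + spread(neg_idx, take_neg, skew=1.8)
    records = [SequenceRecord(id=wild_type_id, sequence=gt.wt_seq,
                              relative_strength=1.0)]
    width = max(3, len(str(n_mutants)))
    for j, i in enumerate(selected, start=1):
        records.append(
            SequenceRecord(
                id=f"m{j:0{width}d}",
                sequence=pool[i],
                relative_strength=float(noisy[i]),
            )
        )
    lib = StrengthLibrary(records=records, wild_type_id=wild_type_id)
    lib.warning_flags = warnings_list
    return lib


# -- ground-truth serialization -------------------------------------------


def save_ground_truth(gt: GroundTruth, path) -> None:
    payload = {
        "wt_seq": gt.wt_seq,
        "site_effects": [
            [pos, base, eff] for (pos, base), eff in sorted(gt.site_effects.items())
        ],
        "noise_sd": gt.noise_sd,
        "s_max": gt.s_max,
        "seed": gt.seed,
        "planted_positive": [list(pb) for pb in gt.planted_positive],
        "planted_negative": [list(pb) for pb in gt.planted_negative],
    }
    Path(path).write_text(json.dumps(payload))


def load_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        wt_seq=payload["wt_seq"],
        site_effects={
            (int(pos), base): float(eff)
            for pos, base, eff in payload["site_effects"]
        },
        noise_sd=payload["noise_sd"],
        s_max=payload["s_max"],
        seed=payload["seed"],
        planted_positive=[(int(p), b) for p, b in payload["planted_positive"]],
        planted_negative=[(int(p), b) for p, b in payload["planted_negative"]],
    )
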