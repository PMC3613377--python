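"""Strength-library I/O and relative-strength arithmetic.

A library is a FASTA file of equal-length sequences plus a TSV table
(``id<TAB>relative_strength``) attaching measured relative strengths.
Strength is dimensionless: blank-subtracted signal of a mutant divided by
the blank-subtracted signal of the wild type, so the wild type is 1 by
definition.
"""

from __future__ import annotations

import io
import math
import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRecord",
    "StrengthLibrary",
    "read_library",
    "write_library",
    "relative_strength",
    "geometric_mean",
]

_WT_STRENGTH_TOL = 1e-9


@dataclass
class SequenceRecord:
    """One library member: an id, a sequence, and (optionally) a strength."""

    id: str
    sequence: str
    relative_strength: float | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.relative_strength is not None:
            self.relative_strength = float(self.relative_strength)
            if self.relative_strength < 0:
                raise ValueError(
                    f"record {self.id!r}: relative_strength must be >= 0, "
                    f"got {self.relative_strength}"
                )


@dataclass
class StrengthLibrary:
    """An ordered collection of equal-length records, one optionally flagged wild type."""

    records: list[SequenceRecord]
    wild_type_id: str | None = None
    warning_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("a StrengthLibrary needs at least one record")
        ids = [r.id for r in self.records]
        seen: set[str] = set()
        for rid in ids:
            if rid in seen:
                raise ValueError(f"duplicate record id {rid!r}")
            seen.add(rid)
        length = len(self.records[0].sequence)
        offenders = [
            r.id for r in self.records if len(r.sequence) != length
        ]
        if offenders:
            raise ValueError(
                f"all sequences must have length {length}; "
                f"offending records: {offenders}"
            )
        if self.wild_type_id is not None:
            wt = self.get(self.wild_type_id)
            if wt is None:
                raise ValueError(
                    f"wild_type_id {self.wild_type_id!r} does not match any record"
                )
            if (
                wt.relative_strength is not None
                and abs(wt.relative_strength - 1.0) > _WT_STRENGTH_TOL
            ):
                raise ValueError(
                    "wild-type relative_strength must be 1, got "
                    f"{wt.relative_strength}"
                )

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def sequence_length(self) -> int:
        return len(self.records[0].sequence)

    def get(self, record_id: str) -> SequenceRecord | None:
        for r in self.records:
            if r.id == record_id:
                return r
        return None

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def strengths(self) -> np.ndarray:
        """Measured strengths as an array; raises if any record is unmeasured."""
        missing = [r.id for r in self.records if r.relative_strength is None]
        if missing:
            raise ValueError(f"records without strength: {missing}")
        return np.array([r.relative_strength for r in self.records], float)

    def subset(self, indices: Iterable[int]) -> "StrengthLibrary":
        """A new library with the records at ``indices`` (order preserved)."""
        records = [self.records[i] for i in indices]
        kept = {r.id for r in records}
        wt = self.wild_type_id if self.wild_type_id in kept else None
        return StrengthLibrary(records=records, wild_type_id=wt)


# -- file formats ----------------------------------------------------------


def read_library(
    fasta_source,
    strength_table_source,
    wild_type_id: str | None = None,
) -> StrengthLibrary:
    """Join a FASTA file and a TSV strength table into a library.

    FASTA headers are matched by their first whitespace-delimited token.
    Records absent from the table carry no strength; table ids without a
    FASTA match are an error. Record order follows the FASTA.
    """
    fasta_records = list(SeqIO.parse(_as_text_handle(fasta_source), "fasta"))
    if not fasta_records:
        raise ValueError("FASTA source contains no records")
    table = pd.read_csv(
        _as_text_handle(strength_table_source), sep="\t",
        float_precision="round_trip",
    )
    expected = {"id", "relative_strength"}
    if not expected.issubset(table.columns):
        raise ValueError(
            f"strength table must have columns {sorted(expected)}, "
            f"got {list(table.columns)}"
        )
    if table["id"].duplicated().any():
        dups = table.loc[table["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate ids in strength table: {dups}")
    strengths = dict(zip(table["id"].astype(str), table["relative_strength"]))
    fasta_ids = {r.id for r in fasta_records}
    orphans = sorted(set(strengths) - fasta_ids)
    if orphans:
        raise ValueError(f"strength table ids with no FASTA record: {orphans}")
    records = [
        SequenceRecord(
            id=r.id,
            sequence=str(r.seq),
            relative_strength=strengths.get(r.id),
        )
        for r in fasta_records
    ]
    return StrengthLibrary(records=records, wild_type_id=wild_type_id)


def write_library(lib: StrengthLibrary, fasta_sink, table_sink) -> None:
    """Write a library as FASTA + TSV so that :func:`read_library` round-trips it.

    Strengths are serialized with :func:`repr` precision (>= 6 significant
    digits), so round-trips are value-exact.
    """
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in lib.records
    ]
    SeqIO.write(seq_records, _as_text_handle(fasta_sink, "w"), "fasta")
    rows = [
        {"id": r.id, "relative_strength": repr(r.relative_strength)}
        for r in lib.records
        if r.relative_strength is not None
    ]
    pd.DataFrame(rows, columns=["id", "relative_strength"]).to_csv(
        _as_text_handle(table_sink, "w"), sep="\t", index=False
    )


def _as_text_handle(source, mode: str = "r"):
    if isinstance(source, (str, Path)):
        return open(source, mode)
    if isinstance(source, io.IOBase) or hasattr(source, "read") or hasattr(source, "write"):
        return source
    raise TypeError(f"cannot open {type(source).__name__} as a file")


# -- strength arithmetic ---------------------------------------------------


def relative_strength(F: float, F_blank: float, F_ref: float) -> float:
    """Blank-subtracted fluorescence ratio ``(F - F_blank) / (F_ref - F_blank)``.

    ``F_ref`` is the wild-type reading, so the wild type maps to exactly 1
    and the blank to exactly 0. Readings below blank (measurement noise)
    clamp to 0 with a warning rather than going negative.

    Raises
    ------
    ValueError
        If ``F_ref <= F_blank`` (degenerate reference).
    """
    if F_ref <= F_blank:
        raise ValueError(
            f"degenerate reference: F_ref ({F_ref}) must exceed F_blank ({F_blank})"
        )
    value = (F - F_blank) / (F_ref - F_blank)
    if value < 0:
        warnings.warn(
            f"reading {F} below blank {F_blank}; clamping relative strength to 0",
            stacklevel=2,
        )
        return 0.0
    return value


def geometric_mean(values: Sequence[float]) -> float:
    """Geometric mean ``exp(mean(log(values)))`` of strictly positive values."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("geometric_mean of an empty collection is undefined")
    if np.any(values <= 0):
        raise ValueError("geometric_mean requires strictly positive values")
    return float(math.exp(np.mean(np.log(values))))
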