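"""Domain types and file I/O for random-number-generation (RNG) task data.

The universal input unit is a :class:`Sequence`: an ordered list of integer
responses on a declared finite alphabet ``1..a`` (the RNG task studied here
uses digits 1-9, so ``a = 9`` is the default throughout).  Sequences are
grouped into labeled :class:`SequenceSet` collections (source ``human`` or
``random``) for the classification benchmark, and algorithmic-complexity
measures consume a :class:`CtmTable` mapping canonical short strings to
coding-theorem complexity values.

Positions are 1-based in documentation and error messages, matching the
verbal indexing conventions of the RNG-task literature.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence as TypingSequence

import numpy as np

__all__ = [
    "Sequence",
    "SequenceSet",
    "CtmTable",
    "PrefixLengthSet",
    "SequenceParseError",
    "CtmFormatError",
    "UndefinedMeasureError",
    "read_sequences",
    "write_sequences",
    "truncate_prefix",
    "load_ctm_table",
    "write_ctm_table",
]

VALID_SOURCES = ("human", "random")


class SequenceParseError(ValueError):
    """A sequence file row could not be parsed (names row and column)."""


class CtmFormatError(ValueError):
    """A complexity-table file violates the expected format."""


class UndefinedMeasureError(ValueError):
    """A measure is undefined on this input (e.g. no repeated response).

    Undefined scores propagate as missing values in batch scoring, never
    as zero.
    """


@dataclass(eq=False)
class Sequence:
    """An ordered sequence of integer responses on the alphabet ``1..a``.

    Parameters
    ----------
    values
        The responses, each in ``1..alphabet_size``.
    alphabet_size
        Number of admissible responses ``a`` (default 9, the digits 1-9).
        The alphabet is declared, not inferred: several measures (e.g. the
        redundancy index) need the task alphabet even when a participant
        never used some responses.
    id
        Opaque string label.
    """

    values: np.ndarray
    alphabet_size: int = 9
    id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("a sequence needs at least one response")
        if self.alphabet_size < 1:
            raise ValueError(f"alphabet_size must be >= 1, got {self.alphabet_size}")
        lo, hi = int(self.values.min()), int(self.values.max())
        if lo < 1 or hi > self.alphabet_size:
            raise ValueError(
                f"sequence {self.id!r}: responses must lie in 1..{self.alphabet_size}, "
                f"found values in {lo}..{hi}"
            )

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Sequence):
            return NotImplemented
        return (
            self.id == other.id
            and self.alphabet_size == other.alphabet_size
            and np.array_equal(self.values, other.values)
        )


@dataclass
class SequenceSet:
    """A labeled collection of sequences (source ``human`` or ``random``)."""

    sequences: list[Sequence]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.labels):
            raise ValueError("sequences and labels must be aligned")
        bad = sorted(set(self.labels) - set(VALID_SOURCES))
        if bad:
            raise ValueError(f"labels must be in {VALID_SOURCES}, got {bad}")
        sizes = {s.alphabet_size for s in self.sequences}
        if len(sizes) > 1:
            raise ValueError(f"all sequences must share one alphabet_size, got {sorted(sizes)}")

    def __len__(self) -> int:
        return len(self.sequences)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SequenceSet):
            return NotImplemented
        return self.labels == other.labels and self.sequences == other.sequences

    @property
    def alphabet_size(self) -> int:
        return self.sequences[0].alphabet_size

    def subset(self, label: str) -> list[Sequence]:
        """All sequences carrying the given source label."""
        return [s for s, l in zip(self.sequences, self.labels) if l == label]

    @staticmethod
    def concat(*sets: "SequenceSet") -> "SequenceSet":
        seqs: list[Sequence] = []
        labels: list[str] = []
        for s in sets:
            seqs.extend(s.sequences)
            labels.extend(s.labels)
        return SequenceSet(seqs, labels)


@dataclass(frozen=True)
class CtmTable:
    """Coding-theorem complexity values for canonical short strings.

    Keys are canonical strings (symbols relabeled ``0, 1, 2, ...`` by order
    of first occurrence); published coding-theorem tables are invariant
    under symbol relabeling, so only the canonical representative of each
    permutation class is stored.  Values are approximations of algorithmic
    (Kolmogorov-Chaitin) complexity in bits, strictly positive.
    """

    entries: Mapping[str, float]
    alphabet_size: int
    max_block_length: int

    def __post_init__(self) -> None:
        from .complexity import canonicalize_block  # local to avoid cycle

        for key, val in self.entries.items():
            if len(key) > self.max_block_length:
                raise CtmFormatError(
                    f"key {key!r} longer than declared max block length "
                    f"{self.max_block_length}"
                )
            if canonicalize_block(key) != key:
                raise CtmFormatError(f"key {key!r} is not in canonical form")
            if not val > 0:
                raise CtmFormatError(f"nonpositive complexity {val} for key {key!r}")

    def lookup(self, canonical: str) -> float:
        """Complexity of a canonical block; raises LookupError if absent."""
        try:
            return self.entries[canonical]
        except KeyError:
            raise LookupError(
                f"block {canonical!r} not covered by the complexity table"
            ) from None

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class PrefixLengthSet:
    """The prefix lengths at which the benchmark evaluates every measure.

    The study design sweeps the first 20, 50 and 100 digits of each
    200-digit sequence plus the complete sequence.
    """

    lengths: tuple[int, ...] = (20, 50, 100, 200)

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("at least one prefix length is required")
        prev = 1
        for n in self.lengths:
            if n < 2:
                raise ValueError(f"prefix lengths must be >= 2, got {n}")
            if n < prev:
                raise ValueError(f"prefix lengths must be nondecreasing: {self.lengths}")
            prev = n

    def validate_against(self, data: SequenceSet) -> None:
        shortest = min(len(s) for s in data.sequences)
        if self.lengths[-1] > shortest:
            raise ValueError(
                f"prefix length {self.lengths[-1]} exceeds the shortest "
                f"available sequence ({shortest} responses)"
            )


# ---------------------------------------------------------------------------
# Sequence file I/O
#
# CSV rows: id, source, v1, ..., vL.  Human-inspectable and close to the
# tabular shape of typical RNG-task data deposits; a column-mapping option
# accommodates external files whose exact layout differs.
# ---------------------------------------------------------------------------


def read_sequences(
    path: str | Path,
    alphabet_size: int = 9,
    infer_alphabet: bool = False,
    column_map: Mapping[str, int] | None = None,
) -> SequenceSet:
    """Read a sequence CSV into a :class:`SequenceSet`, preserving row order.

    Each row holds ``id, source, v1, ..., vL``.  ``column_map`` may remap
    the ``id`` and ``source`` columns and the first value column, e.g.
    ``{"id": 0, "source": 1, "values": 2}`` (the default layout), for
    external deposits with a different column order.

    Parameters
    ----------
    alphabet_size
        Declared alphabet ``a``; every value must lie in ``1..a``.
    infer_alphabet
        If True, take ``a`` as the maximum observed value instead
        (explicit opt-in; the declared alphabet is the default because
        measures need the task alphabet even for unused responses).
    """
    cmap = {"id": 0, "source": 1, "values": 2}
    if column_map:
        cmap.update(column_map)
    rows: list[tuple[str, str, list[int]]] = []
    with open(path, newline="") as fh:
        for rownum, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                seq_id = row[cmap["id"]].strip()
                source = row[cmap["source"]].strip()
            except IndexError:
                raise SequenceParseError(
                    f"row {rownum}: fewer columns than the id/source layout requires"
                ) from None
            values: list[int] = []
            for colnum in range(cmap["values"], len(row)):
                token = row[colnum].strip()
                if not token:
                    continue
                try:
                    values.append(int(token))
                except ValueError:
                    raise SequenceParseError(
                        f"row {rownum}, column {colnum + 1}: "
                        f"non-integer token {token!r}"
                    ) from None
            if not values:
                raise SequenceParseError(f"row {rownum}: no response values")
            rows.append((seq_id, source, values))
    if not rows:
        raise SequenceParseError(f"{path}: no sequence rows found")
    lengths = {len(v) for _, _, v in rows}
    if len(lengths) > 1:
        raise SequenceParseError(
            f"{path}: ragged rows — sequence lengths {sorted(lengths)} differ"
        )
    if infer_alphabet:
        alphabet_size = max(max(v) for _, _, v in rows)
    sequences = []
    for seq_id, _, values in rows:
        try:
            sequences.append(Sequence(values, alphabet_size=alphabet_size, id=seq_id))
        except ValueError as exc:
            raise SequenceParseError(str(exc)) from None
    return SequenceSet(sequences, [source for _, source, _ in rows])


def write_sequences(data: SequenceSet, path: str | Path) -> None:
    """Write a :class:`SequenceSet` as CSV rows ``id, source, v1..vL``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for seq, label in zip(data.sequences, data.labels):
            writer.writerow([seq.id, label, *seq.values.tolist()])


def truncate_prefix(seq: Sequence, n: int) -> Sequence:
    """The first ``n`` responses of a sequence (same alphabet and id).

    The benchmark applies this to evaluate each measure on the first 20,
    50 and 100 digits of the full-length sequences.
    """
    if not 1 <= n <= len(seq):
        raise ValueError(
            f"prefix length {n} out of range 1..{len(seq)} for sequence {seq.id!r}"
        )
    return Sequence(seq.values[:n].copy(), alphabet_size=seq.alphabet_size, id=seq.id)


# ---------------------------------------------------------------------------
# Complexity-table I/O
#
# TSV with header lines "#alphabet=<a>" and "#maxlen=<m>", then rows of
# canonical string <TAB> complexity value.
# ---------------------------------------------------------------------------


def load_ctm_table(path: str | Path) -> CtmTable:
    """Load a coding-theorem complexity table from TSV."""
    alphabet: int | None = None
    maxlen: int | None = None
    entries: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    body_started = False
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if body_started:
                raise CtmFormatError(f"line {lineno}: header line after table body")
            key, _, val = line[1:].partition("=")
            key = key.strip().lower()
            if key == "alphabet":
                alphabet = int(val)
            elif key == "maxlen":
                maxlen = int(val)
            else:
                raise CtmFormatError(f"line {lineno}: unknown header field {key!r}")
            continue
        body_started = True
        parts = line.split("\t")
        if len(parts) != 2:
            raise CtmFormatError(f"line {lineno}: expected 'block<TAB>value'")
        block, raw = parts
        try:
            value = float(raw)
        except ValueError:
            raise CtmFormatError(
                f"line {lineno}: non-numeric complexity {raw!r}"
            ) from None
        if block in entries:
            raise CtmFormatError(f"line {lineno}: duplicate key {block!r}")
        entries[block] = value
    if alphabet is None or maxlen is None:
        raise CtmFormatError(
            f"{path}: missing '#alphabet=' or '#maxlen=' header line"
        )
    return CtmTable(entries=entries, alphabet_size=alphabet, max_block_length=maxlen)


def write_ctm_table(table: CtmTable, path: str | Path) -> None:
    """Write a complexity table in the TSV format `load_ctm_table` reads."""
    with open(path, "w") as fh:
        fh.write(f"#alphabet={table.alphabet_size}\n")
        fh.write(f"#maxlen={table.max_block_length}\n")
        for key in sorted(table.entries, key=lambda k: (len(k), k)):
            fh.write(f"{key}\t{table.entries[key]!r}\n")
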