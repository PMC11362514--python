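"""Algorithmic-complexity measures: CTM lookups, BDM, LZ76, DEFLATE length.

Coding-theorem-method (CTM) complexity values for short blocks are
consumed from a lookup table (:class:`~rngbench.core.CtmTable`); published
tables index permutation classes, so every window is canonicalized
(symbols relabeled by first occurrence) before lookup.  Two sequence-level
aggregates are built on the table: the mean window complexity and the
block decomposition method (BDM), which counts each distinct block once
and penalizes recurrences only logarithmically.

Two table-free measures complete the group: the Lempel-Ziv 1976 phrase
count under the Kaspar-Schuster exhaustive-history parse, and the
DEFLATE-compressed byte length of the digit string.  Fewer phrases /
fewer bytes = more compressible = less random.
"""

from __future__ import annotations

import zlib
from collections import Counter
from math import log2
from typing import Iterable, Sequence as TypingSequence

import numpy as np

from .core import CtmTable, Sequence

__all__ = [
    "canonicalize_block",
    "acss_mean_complexity",
    "bdm",
    "lz76_complexity",
    "deflate_length",
    "synthetic_ctm_table",
    "enumerate_canonical_blocks",
    "coding_length",
]

# symbol glyphs for canonical strings; alphabets beyond 36 are not a use case
_GLYPHS = "0123456789abcdefghijklmnopqrstuvwxyz"


def canonicalize_block(block: TypingSequence[int] | str) -> str:
    """Relabel symbols by order of first occurrence and render as a string.

    E.g. 4-1-5-4 -> "0120" and 9-9-9 -> "000".  Strings are treated as
    symbol sequences, so the function is idempotent.
    """
    if len(block) == 0:
        raise ValueError("cannot canonicalize an empty block")
    mapping: dict[object, str] = {}
    out = []
    for sym in block:
        if sym not in mapping:
            mapping[sym] = _GLYPHS[len(mapping)]
        out.append(mapping[sym])
    return "".join(out)


def _canonical_windows(seq: Sequence, k: int) -> list[str]:
    if not 2 <= k <= 10:
        raise ValueError(f"block length must be in 2..10, got {k}")
    if k > len(seq):
        raise ValueError(f"block length {k} exceeds sequence length {len(seq)}")
    v = seq.values.tolist()
    return [canonicalize_block(v[i : i + k]) for i in range(len(v) - k + 1)]


def _check_table(seq: Sequence, k: int, table: CtmTable) -> None:
    if table.alphabet_size < min(seq.alphabet_size, k):
        raise ValueError(
            f"complexity table alphabet {table.alphabet_size} cannot cover "
            f"windows of length {k} over a {seq.alphabet_size}-symbol task alphabet"
        )
    if k > table.max_block_length:
        raise ValueError(
            f"block length {k} exceeds the table's max block length "
            f"{table.max_block_length}"
        )


def acss_mean_complexity(seq: Sequence, k: int, table: CtmTable) -> float:
    """Mean CTM complexity (bits) over the overlapping length-``k`` windows.

    Each window is canonicalized and looked up in the table; the mean over
    all ``W = L - k + 1`` windows is the sequence-level aggregate.
    Raises LookupError (naming the block) if a window is not covered.
    """
    _check_table(seq, k, table)
    windows = _canonical_windows(seq, k)
    return float(np.mean([table.lookup(w) for w in windows]))


def bdm(seq: Sequence, k: int, table: CtmTable) -> float:
    """Block decomposition method complexity (bits) at block length ``k``.

    Over the multiset of canonicalized windows with distinct blocks ``b``
    and multiplicities ``m_b``:  ``BDM = sum_b [K(b) + log2 m_b]``.  Each
    distinct block contributes its full CTM complexity once; recurrences
    add only the logarithm of the block's frequency, so repetitive
    sequences score lower than the plain window sum.
    """
    _check_table(seq, k, table)
    multiplicity = Counter(_canonical_windows(seq, k))
    return float(
        sum(table.lookup(b) + log2(m) for b, m in multiplicity.items())
    )


def lz76_complexity(seq: Sequence) -> int:
    """Lempel-Ziv 1976 phrase count (Kaspar-Schuster exhaustive history).

    Parses the sequence into consecutive phrases, each the shortest
    extension not reproducible from the prior history, and returns the
    number of phrases.  1-1-1-1-1-1 parses as 1 / 11111 (2 phrases);
    1-2-1-2-1-2-1-2 as 1 / 2 / 121212 (3 phrases).  Lower counts mean a
    more compressible, less random sequence.
    """
    s = seq.values.tolist()
    n = len(s)
    # Kaspar & Schuster's pointer formulation of the LZ76 parse
    c = 1  # phrase count; the first symbol is always a new phrase
    i = 0  # start of the current phrase candidate's match search
    k = 1  # current extension length
    l = 1  # start of the current phrase
    k_max = 1
    if n == 1:
        return 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            k_max = max(k, k_max)
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i = 0
                k = 1
                k_max = 1
            else:
                k = 1
    return c


def deflate_length(seq: Sequence, level: int = 9) -> int:
    """Compressed byte count of the digit string under raw DEFLATE.

    Each response is encoded as a single ASCII character (mirroring
    compression of the printed digit string) and compressed as a bare
    DEFLATE stream (no container header or checksum) at a fixed level,
    so the count is deterministic across runs and platforms.  The
    absolute byte count is meaningful only as an ordinal score.
    """
    if seq.alphabet_size > len(_GLYPHS):
        raise ValueError("alphabet too large for single-character encoding")
    text = "".join(_GLYPHS[v] for v in seq.values)
    compressor = zlib.compressobj(level, zlib.DEFLATED, -zlib.MAX_WBITS)
    return len(compressor.compress(text.encode("ascii")) + compressor.flush())


# ---------------------------------------------------------------------------
# Synthetic complexity tables
#
# The published CTM tables (distributed with the acss ecosystem) are an
# optional external input.  For self-contained runs and tests the package
# builds a synthetic stand-in: each canonical block is assigned the length
# of a simple adaptive prefix code (new symbols cost log2(a) bits plus a
# 1-bit novelty flag, repeats cost the log of the number of symbols seen so
# far).  This is not a coding-theorem approximation, but it shares the
# properties the measures rely on: strictly positive, relabeling-invariant,
# and increasing with the diversity of symbols within a block.
# ---------------------------------------------------------------------------


def coding_length(canonical: str, alphabet_size: int) -> float:
    """Adaptive prefix-code length (bits) of a canonical block.

    First symbol: ``log2(a)``.  Each later symbol: a 1-bit new/old flag
    plus ``log2(a)`` if the symbol is new, else ``log2(d)`` where ``d`` is
    the number of distinct symbols seen so far.  Strictly positive and
    monotone in within-block symbol diversity.
    """
    if alphabet_size < 2:
        raise ValueError("coding length requires an alphabet of at least 2")
    cost = log2(alphabet_size)
    seen = {canonical[0]}
    for sym in canonical[1:]:
        if sym in seen:
            cost += 1.0 + log2(len(seen))
        else:
            cost += 1.0 + log2(alphabet_size)
            seen.add(sym)
    return cost


def enumerate_canonical_blocks(
    alphabet_size: int, length: int
) -> Iterable[str]:
    """All canonical strings of the given length using <= a distinct symbols.

    These are restricted-growth strings: each position may reuse a seen
    symbol or introduce the next unused one.  Their number grows like the
    Bell numbers, so enumerate only short lengths.
    """
    def extend(prefix: list[int], distinct: int):
        if len(prefix) == length:
            yield "".join(_GLYPHS[i] for i in prefix)
            return
        for sym in range(min(distinct + 1, alphabet_size)):
            yield from extend(prefix + [sym], max(distinct, sym + 1))

    yield from extend([], 0)


def synthetic_ctm_table(
    sequences: Iterable[Sequence] | None = None,
    block_lengths: Iterable[int] = range(2, 11),
    alphabet_size: int = 9,
    full_upto: int | None = None,
) -> CtmTable:
    """Build a synthetic complexity table (see module notes above).

    If ``sequences`` is given, the table covers exactly the canonical
    windows occurring in them at the requested block lengths — compact
    even for block length 10, where full enumeration is infeasible.
    ``full_upto`` instead (or additionally) enumerates *all* canonical
    blocks up to that length (keep it small, <= 6 for a 9-symbol task).
    """
    block_lengths = sorted(set(block_lengths))
    entries: dict[str, float] = {}
    if full_upto is not None:
        for k in range(2, full_upto + 1):
            for block in enumerate_canonical_blocks(alphabet_size, k):
                entries[block] = coding_length(block, alphabet_size)
    if sequences is not None:
        for seq in sequences:
            for k in block_lengths:
                if k > len(seq):
                    continue
                for w in _canonical_windows(seq, k):
                    if w not in entries:
                        entries[w] = coding_length(w, alphabet_size)
    if not entries:
        raise ValueError("synthetic table would be empty; pass sequences or full_upto")
    max_len = max(len(b) for b in entries)
    return CtmTable(entries=entries, alphabet_size=alphabet_size, max_block_length=max_len)
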