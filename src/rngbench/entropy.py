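"""Block (n-gram) entropy of response sequences.

Block entropy extends single-response Shannon entropy to overlapping
blocks of ``k`` consecutive responses, detecting inequality in the use of
response *patterns* — e.g. a favourite triplet like 7-4-1 lowers the
block-3 entropy even when single-response usage is perfectly even.
Block length 1 is deliberately excluded: it reduces to the information
content already captured by the redundancy index.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .core import Sequence

__all__ = ["BlockDistribution", "block_distribution", "block_entropy"]

MIN_BLOCK, MAX_BLOCK = 2, 10


@dataclass(frozen=True)
class BlockDistribution:
    """Frequencies of the ``W = L - k + 1`` overlapping length-k windows."""

    k: int
    counts: dict[tuple[int, ...], int]

    @property
    def n_windows(self) -> int:
        return sum(self.counts.values())


def block_distribution(seq: Sequence, k: int) -> BlockDistribution:
    """Count the overlapping length-``k`` windows (step 1, no wrap)."""
    if not MIN_BLOCK <= k <= MAX_BLOCK:
        raise ValueError(f"block length must be in {MIN_BLOCK}..{MAX_BLOCK}, got {k}")
    if k > len(seq):
        raise ValueError(f"block length {k} exceeds sequence length {len(seq)}")
    v = seq.values
    counts = Counter(tuple(v[i : i + k].tolist()) for i in range(len(v) - k + 1))
    return BlockDistribution(k=k, counts=dict(counts))


def block_entropy(seq: Sequence, k: int) -> float:
    """Shannon entropy (bits) of the overlapping length-``k`` window counts.

    ``H_k = -sum_b p_b log2 p_b`` with ``p_b = count_b / W``.  0 iff all
    windows are identical (e.g. a constant sequence); the maximum is
    ``log2(min(a**k, W))`` when every window is distinct or all blocks
    are equally frequent.
    """
    dist = block_distribution(seq, k)
    counts = np.fromiter(dist.counts.values(), dtype=float)
    p = counts / dist.n_windows
    return float(-np.sum(p * np.log2(p))) + 0.0
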