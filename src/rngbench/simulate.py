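"""Synthetic sequence populations for the classification benchmark.

Two populations are generated: uniform i.i.d. digit sequences, standing in
for a truly random source, and "human-like" sequences reproducing the
sequential biases documented for human random-number generation —
repetition avoidance (immediate repeats are under-produced), adjacency /
seriation bias (prepotent pairs like 4-5 and 7-6, and continued
arithmetic runs), and cycling (recently unused responses are favoured,
covering the alphabet faster than chance).

The human-like generator is a synthetic stand-in: its parameters are not
fitted to any participant sample, only calibrated so that the default
benchmark reproduces the qualitative ordering of measure sensitivities
expected for real RNG-task data.  Outputs are labelled accordingly.

A small utility, :func:`de_bruijn_sequence`, produces the order-2
de Bruijn extreme case (every ordered pair exactly once) used by
pair-based measures as an analytic lower-bound fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Sequence, SequenceSet

__all__ = [
    "HumanBiasParams",
    "GeneratorSpec",
    "generate_uniform",
    "generate_human_like",
    "de_bruijn_sequence",
]


@dataclass(frozen=True)
class HumanBiasParams:
    """Bias strengths of the human-like generator.

    repetition_penalty
        Multiplier in [0, 1] on the weight of the immediately preceding
        response; below 1 produces repetition avoidance, 0 forbids
        immediate repeats entirely.
    adjacency_boost
        Multiplier >= 1 on the weights of the two responses numerically
        adjacent (+/-1) to the previous one; above 1 produces
        prepotent-associate pairs.
    recency_exponent
        gamma >= 0; each response's weight is proportional to
        ``(steps since last use) ** gamma``, so gamma > 0 produces
        cycling (over-equalized coverage of the alphabet).
    seriation_prob
        Probability in [0, 1] of deterministically continuing the
        arithmetic progression of the last two responses (e.g. 4, 5 -> 6)
        when the continuation lies inside the alphabet.

    The neutral setting (1, 1, 0, 0) reduces the generator exactly to the
    uniform i.i.d. source.  The defaults are a synthetic calibration, not
    estimates from human data.
    """

    repetition_penalty: float = 0.4
    adjacency_boost: float = 1.5
    recency_exponent: float = 0.6
    seriation_prob: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.repetition_penalty <= 1.0:
            raise ValueError("repetition_penalty must lie in [0, 1]")
        if self.adjacency_boost < 1.0:
            raise ValueError("adjacency_boost must be >= 1")
        if self.recency_exponent < 0.0:
            raise ValueError("recency_exponent must be >= 0")
        if not 0.0 <= self.seriation_prob <= 1.0:
            raise ValueError("seriation_prob must lie in [0, 1]")

    @classmethod
    def neutral(cls) -> "HumanBiasParams":
        """Parameters that reduce the generator to uniform i.i.d. draws."""
        return cls(1.0, 1.0, 0.0, 0.0)


@dataclass(frozen=True)
class GeneratorSpec:
    """Dimensions and seed of one generated population.

    The study-scale population is 830 sequences of 200 digits over 1..9
    per source; those are the defaults.
    """

    n: int = 830
    length: int = 200
    alphabet_size: int = 9
    seed: int = 0
    population: str = "uniform"
    params: HumanBiasParams = field(default_factory=HumanBiasParams)

    def __post_init__(self) -> None:
        if self.n < 1 or self.length < 1 or self.alphabet_size < 1:
            raise ValueError(
                f"invalid generator dimensions n={self.n}, length={self.length}, "
                f"alphabet_size={self.alphabet_size}"
            )
        if self.population not in ("uniform", "human_like"):
            raise ValueError(f"unknown population {self.population!r}")


def generate_uniform(spec: GeneratorSpec) -> SequenceSet:
    """n sequences of L i.i.d. uniform draws on 1..a, labelled ``random``.

    Reproducible for a fixed seed (PCG64 via numpy's default generator,
    recorded in the sequence ids).
    """
    rng = np.random.default_rng(spec.seed)
    draws = rng.integers(1, spec.alphabet_size + 1, size=(spec.n, spec.length))
    sequences = [
        Sequence(draws[i], alphabet_size=spec.alphabet_size, id=f"r{spec.seed}_{i:04d}")
        for i in range(spec.n)
    ]
    return SequenceSet(sequences, ["random"] * spec.n)


def generate_human_like(spec: GeneratorSpec) -> SequenceSet:
    """n human-biased sequences, labelled ``human`` (synthetic stand-in).

    The first response is uniform.  Each later response is drawn with
    weights ``w_j = t_j**gamma * (rho if j == prev else 1) * (alpha if
    |j - prev| == 1 else 1)`` where ``t_j`` is the number of steps since
    ``j`` was last used (``L`` for a never-used response, the maximal
    recency weight).  With probability sigma the arithmetic continuation
    of the last two responses is forced instead, when it lies in 1..a.
    """
    p = spec.params
    a, L = spec.alphabet_size, spec.length
    rng = np.random.default_rng(spec.seed)
    symbols = np.arange(1, a + 1)
    sequences = []
    for i in range(spec.n):
        values = np.empty(L, dtype=np.int64)
        last_used = np.full(a, -1, dtype=np.int64)  # step index of last use
        values[0] = rng.integers(1, a + 1)
        last_used[values[0] - 1] = 0
        for step in range(1, L):
            prev = values[step - 1]
            if step >= 2 and p.seriation_prob > 0 and rng.random() < p.seriation_prob:
                cont = prev + (prev - values[step - 2])
                if 1 <= cont <= a:
                    values[step] = cont
                    last_used[cont - 1] = step
                    continue
            t = np.where(last_used >= 0, step - last_used, L).astype(float)
            w = t**p.recency_exponent
            w[prev - 1] *= p.repetition_penalty
            if prev >= 2:
                w[prev - 2] *= p.adjacency_boost
            if prev <= a - 1:
                w[prev] *= p.adjacency_boost
            cum = np.cumsum(w)
            if cum[-1] == 0.0:  # rho=0 on a 1-symbol alphabet only
                cum = np.cumsum(np.ones(a))
            # inverse-CDF draw (faster than Generator.choice in a tight loop)
            idx = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
            values[step] = symbols[idx]
            last_used[idx] = step
        sequences.append(
            Sequence(values, alphabet_size=a, id=f"h{spec.seed}_{i:04d}")
        )
    return SequenceSet(sequences, ["human"] * spec.n)


def de_bruijn_sequence(alphabet_size: int, order: int = 2) -> Sequence:
    """Linearized de Bruijn sequence: every length-``order`` block once.

    Generated with the standard Lyndon-word (FKM) construction over
    symbols 1..a, then linearized by appending the first ``order - 1``
    symbols, so that every ordered block of the given order occurs
    exactly once without wrap-around.  For order 2 over 1..9 this is the
    82-digit sequence in which all 81 ordered pairs occur exactly once —
    the analytic lower-bound input for the RNG index and the NSQ.
    """
    if alphabet_size < 2 or order < 1:
        raise ValueError("need alphabet_size >= 2 and order >= 1")
    a = [0] * alphabet_size * order
    cyclic: list[int] = []

    def build(t: int, p: int) -> None:
        if t > order:
            if order % p == 0:
                cyclic.extend(a[1 : p + 1])
        else:
            a[t] = a[t - p]
            build(t + 1, p)
            for j in range(a[t - p] + 1, alphabet_size):
                a[t] = j
                build(t + 1, t)

    build(1, 1)
    values = [s + 1 for s in cyclic] + [s + 1 for s in cyclic[: order - 1]]
    return Sequence(
        values, alphabet_size=alphabet_size, id=f"debruijn_a{alphabet_size}_n{order}"
    )
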