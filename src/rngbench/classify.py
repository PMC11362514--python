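"""Bootstrapped logistic classification benchmark for randomness measures.

Each measure is evaluated by how well a univariate logistic regression
(intercept + slope on the measure's score) separates human-generated from
random sequences.  The model is bootstrapped: on each of B iterations a
resample of the full dataset size is drawn with replacement, the model is
fitted on the resample, and the correct classification rate (CCR) is
scored on the out-of-bag sequences (those never drawn, on average ~36.8%
of the data).  The B out-of-bag rates yield a mean rate and a 95%
percentile confidence interval; two measures whose intervals do not
overlap differ significantly, and a measure whose interval covers 0.50
performs at chance.

The benchmark sweeps every measure over prefix lengths (first 20, 50 and
100 digits plus the complete sequence, by default) and also reports the
common language effect size (CLES): the probability that a random human
score exceeds a random random-source score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence as TypingSequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from . import complexity, entropy, psych
from .core import (
    CtmTable,
    PrefixLengthSet,
    Sequence,
    SequenceSet,
    UndefinedMeasureError,
    truncate_prefix,
)

__all__ = [
    "MeasureDef",
    "ClassificationResult",
    "default_battery",
    "score_sequences",
    "bootstrap_ccr",
    "cles",
    "run_benchmark",
    "cis_nonoverlapping",
    "significant_pairs",
]

# Ridge stabilization for the logistic fits: the penalty is tiny (C = 1e4)
# so coefficients are effectively unpenalized, but perfectly separated
# training draws still converge; threshold decisions are insensitive to it.
_LOGIT_C = 1e4


@dataclass(frozen=True)
class MeasureDef:
    """One cell of the measure battery: a named, parameterized scorer."""

    measure: str
    variant: str | None
    fn: Callable[[Sequence], float]
    needs_table: bool = False

    @property
    def key(self) -> str:
        return self.measure if self.variant is None else f"{self.measure}[{self.variant}]"


def default_battery(table: CtmTable | None = None) -> list[MeasureDef]:
    """The full measure battery evaluated by the benchmark.

    CTM-dependent measures (mean short-block complexity and BDM, block
    lengths 2-10) are included only when a complexity table is supplied.
    """
    defs: list[MeasureDef] = [
        MeasureDef("redundancy", None, psych.redundancy_index),
        MeasureDef("rng", None, lambda s: psych.rng_index(s, lag=1)),
        MeasureDef("rng2", None, lambda s: psych.rng_index(s, lag=2)),
        MeasureDef("nsq", None, psych.null_score_quotient),
        MeasureDef("coupon", None, psych.coupon_score),
    ]
    for stat in ("mean", "median", "mode"):
        defs.append(
            MeasureDef(
                "repetition_gap", stat,
                lambda s, stat=stat: psych.repetition_gap(s, statistic=stat),
            )
        )
    for mode in ("ascending", "descending", "combined"):
        defs.append(
            MeasureDef(
                "adjacency", mode,
                lambda s, mode=mode: psych.adjacency_index(s, mode=mode),
            )
        )
    defs.append(MeasureDef("turning_point", None, psych.turning_point_index))
    defs.append(MeasureDef("runs", None, psych.runs_index))
    for d in range(2, 11):
        defs.append(
            MeasureDef("phi", str(d), lambda s, d=d: psych.phi_index(s, d=d))
        )
    for k in range(2, 11):
        defs.append(
            MeasureDef(
                "block_entropy", str(k),
                lambda s, k=k: entropy.block_entropy(s, k=k),
            )
        )
    if table is not None:
        for k in range(2, 11):
            defs.append(
                MeasureDef(
                    "acss_mean", str(k),
                    lambda s, k=k: complexity.acss_mean_complexity(s, k, table),
                    needs_table=True,
                )
            )
            defs.append(
                MeasureDef(
                    "bdm", str(k),
                    lambda s, k=k: complexity.bdm(s, k, table),
                    needs_table=True,
                )
            )
    defs.append(MeasureDef("lz76", None, lambda s: float(complexity.lz76_complexity(s))))
    defs.append(MeasureDef("deflate_bytes", None, lambda s: float(complexity.deflate_length(s))))
    return defs


def score_sequences(
    data: SequenceSet,
    lengths: PrefixLengthSet | Iterable[int],
    measures: TypingSequence[MeasureDef],
) -> pd.DataFrame:
    """Per-sequence measure scores in long format.

    Columns: measure, variant, prefix_length, sequence_id, label, score.
    Measures that are undefined on an input (e.g. the repetition gap of a
    sequence without any repeat) or whose preconditions a short prefix
    violates are recorded as missing (NaN), never as zero.
    """
    if not isinstance(lengths, PrefixLengthSet):
        lengths = PrefixLengthSet(tuple(lengths))
    lengths.validate_against(data)
    rows: list[tuple] = []
    for seq, label in zip(data.sequences, data.labels):
        for n in lengths.lengths:
            prefix = truncate_prefix(seq, n)
            for mdef in measures:
                try:
                    score = float(mdef.fn(prefix))
                except (UndefinedMeasureError, ValueError):
                    score = math.nan
                rows.append((mdef.measure, mdef.variant, n, seq.id, label, score))
    return pd.DataFrame(
        rows,
        columns=["measure", "variant", "prefix_length", "sequence_id", "label", "score"],
    )


@dataclass(frozen=True)
class ClassificationResult:
    """Bootstrap CCR summary for one measure x prefix-length cell."""

    mean_rate: float
    ci_low: float
    ci_high: float
    rates: np.ndarray
    b: int
    seed: int
    n_used: int
    n_excluded: int
    measure: str = ""
    variant: str | None = None
    prefix_length: int | None = None


def _fit_predict(
    train_x: np.ndarray, train_y: np.ndarray, test_x: np.ndarray
) -> np.ndarray:
    """Fit the univariate logistic model and classify the test scores.

    Degenerate training draws (zero score variance or a single class)
    carry no usable signal; callers handle them before reaching here.
    Predicted probability exactly 0.5 classifies as the random source.
    """
    model = LogisticRegression(C=_LOGIT_C, solver="lbfgs", max_iter=1000)
    model.fit(train_x.reshape(-1, 1), train_y)
    prob_human = model.predict_proba(test_x.reshape(-1, 1))[:, list(model.classes_).index(1)]
    return (prob_human > 0.5).astype(int)


def bootstrap_ccr(
    scores: TypingSequence[float] | np.ndarray,
    labels: TypingSequence[str] | np.ndarray,
    b: int = 1000,
    seed: int | None = None,
) -> ClassificationResult:
    """Bootstrap the out-of-bag correct classification rate of one measure.

    Each of ``b`` iterations draws ``n`` indices with replacement
    (``n`` = dataset size after exclusion of missing scores), fits the
    logistic model on the draw, and scores the out-of-bag sequences at
    probability threshold 0.5.  Iterations whose out-of-bag set is empty
    are redrawn; a training draw with zero score variance or only one
    class is uninformative and contributes the chance rate 0.5.

    Returns the mean rate and the 2.5th/97.5th percentile interval over
    the ``b`` rates.  Bit-for-bit reproducible for a fixed seed.
    """
    if b < 2:
        raise ValueError(f"need at least 2 bootstrap iterations, got {b}")
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l == "human" else 0 for l in labels], dtype=int)
    if scores.shape != y.shape:
        raise ValueError("scores and labels must be aligned")
    keep = ~np.isnan(scores)
    n_excluded = int(np.sum(~keep))
    scores, y = scores[keep], y[keep]
    n = scores.size
    if len(np.unique(y)) < 2:
        raise ValueError("both source classes must be present")
    rng = np.random.default_rng(seed)
    rates = np.empty(b)
    for it in range(b):
        while True:
            idx = rng.integers(0, n, size=n)
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            if oob.any():
                break
        train_x, train_y = scores[idx], y[idx]
        if np.ptp(train_x) == 0.0 or len(np.unique(train_y)) < 2:
            rates[it] = 0.5
            continue
        pred = _fit_predict(train_x, train_y, scores[oob])
        rates[it] = float(np.mean(pred == y[oob]))
    ci_low, ci_high = np.percentile(rates, [2.5, 97.5])
    return ClassificationResult(
        mean_rate=float(rates.mean()),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        rates=rates,
        b=b,
        seed=-1 if seed is None else int(seed),
        n_used=n,
        n_excluded=n_excluded,
    )


def cles(
    human_scores: TypingSequence[float] | np.ndarray,
    random_scores: TypingSequence[float] | np.ndarray,
) -> float:
    """Common language effect size: P(random human score > random random score).

    Ties count one half.  Equivalent to the probability-of-superiority
    reading of the Mann-Whitney U statistic.
    """
    h = np.asarray(human_scores, dtype=float)
    r = np.asarray(random_scores, dtype=float)
    h, r = h[~np.isnan(h)], r[~np.isnan(r)]
    if h.size == 0 or r.size == 0:
        raise ValueError("both score samples must be nonempty")
    diff = h[:, None] - r[None, :]
    wins = np.sum(diff > 0) + 0.5 * np.sum(diff == 0)
    return float(wins / (h.size * r.size))


def run_benchmark(
    data: SequenceSet,
    lengths: PrefixLengthSet | Iterable[int] = (20, 50, 100, 200),
    measures: TypingSequence[MeasureDef] | None = None,
    table: CtmTable | None = None,
    b: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every measure at every prefix length and bootstrap its CCR.

    Returns a long-format report with one row per measure x variant x
    prefix-length cell: mean out-of-bag CCR, 95% percentile CI, CLES,
    iteration count, exclusion count, and the cell seed.  Cell seeds are
    spawned deterministically from ``seed``, so the full report is
    reproducible bit for bit.
    """
    if measures is None:
        measures = default_battery(table)
    if any(m.needs_table for m in measures) and table is None:
        raise ValueError("CTM-dependent measures requested but no complexity table given")
    if len(set(data.labels)) < 2:
        raise ValueError("benchmark data must contain both source labels")
    scores = score_sequences(data, lengths, measures)
    rows = []
    cells = list(scores.groupby(["measure", "variant", "prefix_length"], dropna=False, sort=True))
    seeds = np.random.SeedSequence(seed).generate_state(len(cells)) % (2**31)
    for ((measure, variant, n), cell), cell_seed in zip(cells, seeds):
        result = bootstrap_ccr(
            cell["score"].to_numpy(), cell["label"].to_numpy(), b=b, seed=int(cell_seed)
        )
        h = cell.loc[cell["label"] == "human", "score"].to_numpy()
        r = cell.loc[cell["label"] == "random", "score"].to_numpy()
        rows.append(
            {
                "measure": measure,
                "variant": None if pd.isna(variant) else variant,
                "prefix_length": int(n),
                "mean_rate": result.mean_rate,
                "ci_low": result.ci_low,
                "ci_high": result.ci_high,
                "cles": cles(h, r),
                "b": b,
                "n_used": result.n_used,
                "n_excluded": result.n_excluded,
                "seed": int(cell_seed),
            }
        )
    return pd.DataFrame(rows)


def cis_nonoverlapping(row_a: pd.Series, row_b: pd.Series) -> bool:
    """Significance rule: two cells differ if their 95% CIs do not overlap."""
    return bool(row_a["ci_high"] < row_b["ci_low"] or row_b["ci_high"] < row_a["ci_low"])


def significant_pairs(report: pd.DataFrame) -> pd.DataFrame:
    """All same-length cell pairs flagged significant by CI non-overlap."""
    rows = []
    for n, group in report.groupby("prefix_length"):
        recs = group.to_dict("records")
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                a, b_ = recs[i], recs[j]
                if a["ci_high"] < b_["ci_low"] or b_["ci_high"] < a["ci_low"]:
                    better, worse = (b_, a) if a["ci_high"] < b_["ci_low"] else (a, b_)
                    rows.append(
                        {
                            "prefix_length": n,
                            "better_measure": better["measure"],
                            "better_variant": better["variant"],
                            "worse_measure": worse["measure"],
                            "worse_variant": worse["variant"],
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "prefix_length",
            "better_measure",
            "better_variant",
            "worse_measure",
            "worse_variant",
        ],
    )
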