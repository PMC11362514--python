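# Methods

This note documents the statistical conventions, parameter choices and
known limitations behind `rngbench`. Notation: a sequence has length
`L`, responses lie on the alphabet `1..a` (default `a = 9`), and `k` (or
`d` for the phi index) denotes a block length in `2..10`.

## Sequences and shared conventions

The alphabet is **declared, not inferred** (inference is an explicit
opt-in of the CSV reader). Measures such as the redundancy index and the
NSQ are defined over all admissible responses, including those a
participant never produced; inferring the alphabet from the data would
silently change their values.

All pair-based measures count pairs **without wrap-around**: the pair
formed by the last and (starting over) the first response is never
counted, so a lag-`g` pair count always totals `L − g`. Everywhere a
term `x log x` appears, `0 · log 0 := 0`. Positions are 1-based in
documentation and error messages.

Measures that are undefined on an input (the repetition gap of a
sequence with no repeated response) raise `UndefinedMeasureError` and
propagate as missing values in batch scoring — never as zero, which
would be a legitimate (extreme) score.

## The psychological battery

- **Redundancy index** `100·(1 − H/log2 a)` with `H` the Shannon
  entropy of single-response frequencies. Bounded in `[0, 100]`; the
  implementation clips float round-off at the ends so the analytic
  extremes (perfect equality → 0, single response → 100) are exact.
- **RNG / RNG2 index** `100 · Σ n_ij log n_ij / Σ n_i· log n_i·` over
  pair counts at lag 1 (RNG) or lag 2 (RNG2). The log base cancels;
  natural log is used internally. When every row sum is 0 or 1 the
  denominator vanishes and the sequence carries no pair information; the
  score is then defined as 0.
- **NSQ** uses denominator `a²` (all ordered pairs, repeats included).
  The alternative `a² − 1` (excluding perfect repeats) exists in the
  literature; `a²` was chosen because no pair is excluded from the
  numerator either.
- **Coupon score**: trailing incomplete segments are discarded; a
  sequence missing some response entirely scores the sentinel `L + 1`.
  Note the score range is `[a, L]` only when all responses occur.
- **Repetition gap**: gaps pooled over all response values; the median
  of an even count is the midpoint average; modal ties break to the
  smallest gap (deterministic and biased toward the short-repeat end,
  where the human signal lives).
- **Adjacency index**: numeric adjacency only, no wrap (9→1 is not
  adjacent). Under i.i.d. uniform digits the combined variant averages
  `100·16/81 ≈ 19.75` (16 adjacent ordered pairs out of 81).
- **Turning point index**: strict extrema only; tied neighbours produce
  no turning point (the tie-collapsed alternative would need an extra
  convention for plateaus; ties are rare for `a = 9` and the strict rule
  is the simpler contract). Expected count `(2/3)(L − 2)`.
- **Runs index**: maximal strictly ascending runs (an equal successor
  starts a new run); population variance of run lengths by default, with
  a `sample` switch.
- **Phi index** at span `d`: `100·(O_d − E_d)/N_d`, where `O_d` counts
  blocks of length `d` whose first and last response coincide,
  `N_d = L − d + 1`, and `E_d = N_d · O_{d−1}/N_{d−1}` for `d ≥ 3`.
  At `d = 2` the one-shorter recursion degenerates (a length-1 block's
  first and last response always coincide), so the expectation is chance
  repetition under the observed marginals, estimated **without bias** as
  `E_2 = N_2 · Σ_s c_s(c_s − 1)/(L(L − 1))`. The plug-in alternative
  `Σ (c_s/L)²` overestimates chance repetition by `(1 − 1/a)/L` and
  would bias the index to ≈ −0.4 at `L = 200` on i.i.d. input; with the
  unbiased form the index averages 0 at every `d` under the i.i.d. null
  (property-tested) while keeping the intended sign contract (negative =
  repetition avoidance) and the saturated-repetition zero case. The
  scale may differ from other published implementations of the index,
  which document only the verbal recursion.

## Block entropy

`H_k = −Σ p_b log2 p_b` over the `W = L − k + 1` overlapping windows
(step 1, no circular wrap, consistent with the pair-count convention).
Base-2 logarithm throughout; the base only rescales scores and cannot
affect classification. `k = 1` is excluded as redundant with the
redundancy index. No bias correction (Miller–Madow etc.) is applied —
the benchmark compares sequences at equal length, where the bias is
common to both populations.

## Algorithmic complexity

CTM complexity values are **inputs**: a lookup table mapping canonical
blocks (first-occurrence relabeling to `0,1,2,…`) to positive values in
bits. The loader accepts externally produced tables (e.g. the published
coding-theorem tables of the acss ecosystem) in a simple TSV format.
For self-contained runs the package builds a clearly-labelled
**synthetic table**: each canonical block is priced by an adaptive
prefix code (first symbol `log2 a`; each later symbol a 1-bit new/old
flag plus `log2 a` if new, else `log2 d` with `d` symbols seen so far).
This is *not* a coding-theorem approximation; it shares the properties
the measures rely on — strictly positive, relabeling-invariant, and
monotone in within-block symbol diversity — and is adequate for
benchmarking measure *behaviour*, not for quoting absolute complexity
values.

BDM uses a base-2 logarithm for the multiplicity penalty
(`Σ_b K(b) + log2 m_b`), consistent with bits. LZ76 returns the raw
Kaspar–Schuster phrase count, no normalization. DEFLATE compression uses
level 9 and a bare stream (no container header or checksum) so byte
counts are deterministic across platforms; digits are encoded as single
ASCII characters, mirroring compression of the printed digit string.
Both compression scores are ordinal.

## Synthetic populations

`generate_uniform` draws i.i.d. uniform digits (PCG64, seeded). The
human-like generator draws each response with weights

```
w_j = t_j^γ · (ρ if j = previous) · (α if |j − previous| = 1)
```

where `t_j` is the number of steps since `j` was last used (`L` for a
never-used response), and with probability `σ` instead forces the
arithmetic continuation of the last two responses when it stays in
range. The first response is uniform. Neutral parameters
`(ρ, α, γ, σ) = (1, 1, 0, 0)` reduce the generator exactly to the
uniform source (property-tested by distribution comparison).

Defaults `ρ = 0.4, α = 1.5, γ = 0.6, σ = 0.1` are a synthetic
calibration chosen so the default benchmark shows the qualitative
sensitivity ordering expected for human data — repetition-gap and
coupon measures strong, turning-point and runs indices weak, early
over-equalization visible in the redundancy index at short prefixes.
They are not estimates from any participant sample, and passing tests on
this generator demonstrates correct measure and benchmark behaviour on
*known* biases, not performance on real human data, which carries
individual differences, drift and strategy changes the generator does
not model.

## Classification benchmark

Per measure and prefix length: `B` bootstrap iterations (study-scale
default 1000), each drawing `n` indices with replacement from the `n`
available sequences (after pairwise exclusion of missing scores, with
exclusion counts reported), fitting a two-parameter logistic model of
source on score, and scoring the out-of-bag sequences (those never
drawn; ≈ 36.8% on average) at probability threshold 0.5. Iterations
with an empty out-of-bag set are redrawn. The reported point estimate is
the **mean** of the `B` out-of-bag rates; the interval is the 2.5th and
97.5th percentile of the same rates.

Numerical choices: the logistic fit carries a tiny ridge penalty
(`C = 10⁴` in scikit-learn's parameterization), which makes perfectly
separated training draws converge without measurably affecting threshold
decisions; a training draw with zero score variance (or a single class)
carries no usable signal and contributes the chance rate 0.5; a
predicted probability of exactly 0.5 classifies as the random source.
Cell seeds are spawned deterministically from the benchmark seed, so the
full report is reproducible bit for bit.

Significance between two cells uses CI non-overlap; no multiple-testing
correction is applied to these flags. CLES is computed by exhaustive
pair enumeration with ties counting one half.

## Problem sizes in the test suite

The automated tests exercise the benchmark at reduced but statistically
adequate sizes chosen as a deliberate trade-off between resolution and
runtime: null-coverage and ordering checks use 200–300 sequences per
class with `B = 200` bootstrap iterations; generator calibration checks
use 300–1000 replicates. Study-scale runs (830 per class, `B = 1000`)
use the identical code path via `run_benchmark` or the CLI.

## Known limitations

- The synthetic complexity table ranks blocks by symbol diversity, not
  by Turing-machine output frequency; absolute CTM/BDM values from it
  are not comparable to published tables.
- The human-like generator is first-order (plus the two-step seriation
  rule); it does not reproduce longer-range human patterns such as
  drifting strategies or favourite multi-digit motifs beyond what the
  bias parameters induce.
- The benchmark evaluates one measure per model by design; it says
  nothing about multivariate combinations of measures.
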