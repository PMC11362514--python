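"""Independent brute-force reimplementations of every measure.

These oracles use naive loops and dictionaries only, deliberately sharing
no code with the package implementations they cross-check.
"""

import math
from collections import Counter


def redundancy(values, a):
    counts = Counter(values)
    h = 0.0
    for s in range(1, a + 1):
        p = counts.get(s, 0) / len(values)
        if p > 0:
            h -= p * math.log2(p)
    return 100.0 * (1.0 - h / math.log2(a))


def rng_index(values, lag):
    pairs = Counter()
    firsts = Counter()
    for i in range(len(values) - lag):
        pairs[(values[i], values[i + lag])] += 1
        firsts[values[i]] += 1
    num = sum(c * math.log(c) for c in pairs.values() if c > 0)
    den = sum(c * math.log(c) for c in firsts.values() if c > 0)
    return 0.0 if den == 0 else 100.0 * num / den


def nsq(values, a):
    present = set()
    for i in range(len(values) - 1):
        present.add((values[i], values[i + 1]))
    absent = sum(
        1 for x in range(1, a + 1) for y in range(1, a + 1) if (x, y) not in present
    )
    return 100.0 * absent / a**2


def coupon(values, a):
    counts = []
    i = 0
    while i < len(values):
        seen = set()
        start = i
        while i < len(values) and len(seen) < a:
            seen.add(values[i])
            i += 1
        if len(seen) == a:
            counts.append(i - start)
        else:
            break
    if not counts:
        return len(values) + 1
    return sum(counts) / len(counts)


def repetition_gaps(values):
    positions = {}
    gaps = []
    for pos, v in enumerate(values, start=1):
        positions.setdefault(v, []).append(pos)
    for plist in positions.values():
        for p, q in zip(plist, plist[1:]):
            gaps.append(q - p)
    return gaps


def gap_statistic(gaps, statistic):
    if statistic == "mean":
        return sum(gaps) / len(gaps)
    if statistic == "median":
        g = sorted(gaps)
        m = len(g) // 2
        return float(g[m]) if len(g) % 2 else (g[m - 1] + g[m]) / 2.0
    best, best_count = None, -1
    for g in sorted(set(gaps)):
        c = gaps.count(g)
        if c > best_count:
            best, best_count = g, c
    return float(best)


def adjacency(values, mode):
    count = 0
    for x, y in zip(values, values[1:]):
        if mode == "ascending" and y == x + 1:
            count += 1
        elif mode == "descending" and y == x - 1:
            count += 1
        elif mode == "combined" and abs(y - x) == 1:
            count += 1
    return 100.0 * count / (len(values) - 1)


def turning_points(values):
    count = 0
    for i in range(1, len(values) - 1):
        if values[i - 1] < values[i] > values[i + 1]:
            count += 1
        elif values[i - 1] > values[i] < values[i + 1]:
            count += 1
    return count


def turning_point_index(values):
    return 100.0 * turning_points(values) / ((2.0 / 3.0) * (len(values) - 2))


def run_lengths(values):
    lengths = []
    current = [values[0]]
    for v in values[1:]:
        if v > current[-1]:
            current.append(v)
        else:
            lengths.append(len(current))
            current = [v]
    lengths.append(len(current))
    return lengths


def runs_variance(values, population=True):
    lengths = run_lengths(values)
    mean = sum(lengths) / len(lengths)
    ss = sum((l - mean) ** 2 for l in lengths)
    if population:
        return ss / len(lengths)
    return ss / (len(lengths) - 1) if len(lengths) > 1 else 0.0


def phi(values, d, a):
    L = len(values)
    n_d = L - d + 1
    o_d = sum(1 for i in range(n_d) if values[i] == values[i + d - 1])
    if d == 2:
        counts = Counter(values)
        e_d = n_d * sum(c * (c - 1) for c in counts.values()) / (L * (L - 1))
    else:
        n_prev = L - d + 2
        o_prev = sum(1 for i in range(n_prev) if values[i] == values[i + d - 2])
        e_d = n_d * o_prev / n_prev
    return 100.0 * (o_d - e_d) / n_d


def block_entropy(values, k):
    counts = Counter(tuple(values[i : i + k]) for i in range(len(values) - k + 1))
    total = sum(counts.values())
    return -sum((c / total) * math.log2(c / total) for c in counts.values())


def canonical(block):
    seen = []
    out = ""
    for sym in block:
        if sym not in seen:
            seen.append(sym)
        out += "0123456789abcdefghijklmnopqrstuvwxyz"[seen.index(sym)]
    return out


def acss_mean(values, k, entries):
    windows = [canonical(values[i : i + k]) for i in range(len(values) - k + 1)]
    return sum(entries[w] for w in windows) / len(windows)


def bdm(values, k, entries):
    windows = [canonical(values[i : i + k]) for i in range(len(values) - k + 1)]
    mult = Counter(windows)
    return sum(entries[b] + math.log2(m) for b, m in mult.items())


def lz76(values):
    """Exhaustive-history parse via substring search: a phrase ends at the
    first extension not occurring inside the prior text."""
    s = "".join(chr(48 + v) for v in values)
    n = len(s)
    c = 0
    start = 0
    while start < n:
        k = 1
        while start + k <= n and s[start : start + k] in s[: start + k - 1]:
            k += 1
        c += 1
        if start + k > n:  # trailing phrase still reproducible
            break
        start += k
    return c


def cles(h, r):
    wins = 0.0
    for x in h:
        for y in r:
            if x > y:
                wins += 1.0
            elif x == y:
                wins += 0.5
    return wins / (len(h) * len(r))
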