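"""Independent oracles used by the test-suite.

Deliberately naive implementations (pure-python per-second tallies,
textbook formulas, exhaustive enumeration) kept separate from the package
so that agreement between the two routes is meaningful.
"""

from __future__ import annotations

import math


def naive_confusion(ref, dev) -> list[list[int]]:
    """Per-second 4x4 tally by explicit iteration."""
    counts = [[0] * 4 for _ in range(4)]
    assert len(ref) == len(dev)
    for r, d in zip(ref, dev):
        counts[int(r)][int(d)] += 1
    return counts


def naive_summary(counts) -> dict:
    """Accuracy, per-stage F1, macro/weighted F1 and kappa from counts."""
    n = sum(sum(row) for row in counts)
    accuracy = sum(counts[s][s] for s in range(4)) / n
    row = [sum(counts[s]) for s in range(4)]
    col = [sum(counts[r][s] for r in range(4)) for s in range(4)]

    f1s = []
    for s in range(4):
        tp = counts[s][s]
        fn = row[s] - tp
        fp = col[s] - tp
        denom = 2 * tp + fp + fn
        f1s.append(0.0 if denom == 0 else 2 * tp / denom)
    macro = sum(f1s) / 4
    weighted = sum(f * r for f, r in zip(f1s, row)) / n

    p_o = accuracy
    p_e = sum(r * c for r, c in zip(row, col)) / (n * n)
    kappa = math.nan if p_e >= 1 else (p_o - p_e) / (1 - p_e)
    return {
        "accuracy": accuracy,
        "f1": f1s,
        "macro_f1": macro,
        "weighted_f1": weighted,
        "kappa": kappa,
    }


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration of the margin-fixed
    tables, summing the probabilities of tables no more probable than the
    observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_fact(k: int) -> float:
        return math.lgamma(k + 1)

    def log_p(x: int) -> float:
        # hypergeometric probability of table [[x, r1-x], [c1-x, r2-c1+x]]
        return (
            log_fact(r1) + log_fact(r2) + log_fact(c1) + log_fact(n - c1)
            - log_fact(n) - log_fact(x) - log_fact(r1 - x)
            - log_fact(c1 - x) - log_fact(r2 - c1 + x)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = log_p(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_p(x)
        if lp <= p_obs + 1e-9:
            total += math.exp(lp)
    return min(1.0, total)
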