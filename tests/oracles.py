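"""Independent brute-force reference implementations used only by tests.

Deliberately written from first principles (explicit loops, no shared
code with the package) so that agreement is evidence of correctness
rather than of shared bugs.
"""
from __future__ import annotations

import math


def brute_ranks(scores) -> list[float]:
    """Descending average ranks by explicit counting."""
    out = []
    for s in scores:
        greater = sum(1 for t in scores if t > s)
        ties = sum(1 for t in scores if t == s)
        out.append(greater + (ties + 1) / 2)
    return out


def brute_kendall_w(matrix) -> float:
    """Tie-corrected W from explicit rank sums and tie groups."""
    rows = [brute_ranks(row) for row in matrix]
    m = len(rows)
    n = len(rows[0])
    rank_sums = [sum(rows[i][j] for i in range(m)) for j in range(n)]
    mean_sum = sum(rank_sums) / n
    s = sum((rs - mean_sum) ** 2 for rs in rank_sums)
    tie_total = 0.0
    for row in rows:
        counts: dict[float, int] = {}
        for r in row:
            counts[r] = counts.get(r, 0) + 1
        for t in counts.values():
            tie_total += t**3 - t
    denom = m * m * (n**3 - n) - m * tie_total
    if denom <= 0:
        return 0.0
    return 12.0 * s / denom


def brute_indicator_stats(scores, full_score, ddof=1) -> dict:
    """Mean, sd, coefficient of variation and full-score rate by loops."""
    n = len(scores)
    mean = sum(scores) / n
    if n - ddof > 0:
        var = sum((x - mean) ** 2 for x in scores) / (n - ddof)
    else:
        var = 0.0
    sd = math.sqrt(var)
    kj = sum(1 for x in scores if x == full_score) / n
    vj = sd / mean if mean != 0 else float("nan")
    return {"Mj": mean, "sd": sd, "Vj": vj, "Kj": kj}
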