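"""Independent brute-force reference implementations used by the tests.

Deliberately written in plain Python (loops, math module) with no
shared code paths with the package, so agreement is meaningful.
"""

from __future__ import annotations

import math


def pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    if sx == 0.0 or sy == 0.0:
        return 0.0  # zero-variance convention
    return sum((a - mx) * (b - my) for a, b in zip(x, y)) / (sx * sy)


def sample_sd(x):
    n = len(x)
    m = sum(x) / n
    return math.sqrt(sum((a - m) ** 2 for a in x) / (n - 1))


def normalized_weights(abs_corrs):
    m = len(abs_corrs)
    total = sum(abs_corrs)
    if total == 0.0:
        return [1.0 / m] * m
    return [c / total for c in abs_corrs]


def entropy(weights):
    m = len(weights)
    return -sum(p * math.log(p) for p in weights if p > 0.0) / m


def local_entropy_from_data(center, neighbors, columns):
    """Entropy of one gene given expression ``columns`` (gene -> list)."""
    absr = [abs(pearson(columns[nb], columns[center])) for nb in neighbors]
    return entropy(normalized_weights(absr))


def score_sample_bruteforce(case, ref, edges):
    """Straight-line per-gene scoring.

    ``case``: gene -> value; ``ref``: gene -> list of reference values;
    ``edges``: iterable of gene pairs. Returns (global_score, per-gene
    dict of (e_ref, e_mixed, d_e, d_sd)).
    """
    adjacency: dict[str, set[str]] = {}
    for a, b in edges:
        if a == b:
            continue
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
    genes = sorted(g for g, nbrs in adjacency.items() if nbrs)

    mixed = {g: list(ref[g]) + [case[g]] for g in genes}
    per_gene = {}
    total = 0.0
    for g in genes:
        nbrs = sorted(adjacency[g])
        e_ref = local_entropy_from_data(g, nbrs, ref)
        e_mix = local_entropy_from_data(g, nbrs, mixed)
        d_e = abs(e_mix - e_ref)
        d_sd = abs(sample_sd(ref[g]) - sample_sd(mixed[g]))
        per_gene[g] = (e_ref, e_mix, d_e, d_sd)
        total += d_e * d_sd
    return total / len(genes), per_gene


def km_bruteforce(times, events):
    """Product-limit estimator: list of (event_time, survival)."""
    out = []
    s = 1.0
    for t in sorted({t for t, e in zip(times, events) if e == 1}):
        at_risk = sum(1 for ti in times if ti >= t)
        deaths = sum(1 for ti, ei in zip(times, events) if ti == t and ei == 1)
        s *= 1.0 - deaths / at_risk
        out.append((t, s))
    return out


def logrank_bruteforce(times_a, events_a, times_b, events_b):
    """Observed-minus-expected tabulation over pooled event times."""
    event_times = sorted(
        {t for t, e in zip(times_a, events_a) if e == 1}
        | {t for t, e in zip(times_b, events_b) if e == 1}
    )
    o_a = e_a = v = 0.0
    for t in event_times:
        n_a = sum(1 for ti in times_a if ti >= t)
        n_b = sum(1 for ti in times_b if ti >= t)
        n = n_a + n_b
        d_a = sum(1 for ti, ei in zip(times_a, events_a) if ti == t and ei == 1)
        d_b = sum(1 for ti, ei in zip(times_b, events_b) if ti == t and ei == 1)
        d = d_a + d_b
        o_a += d_a
        e_a += d * n_a / n
        if n > 1:
            v += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    if v == 0.0:
        return 0.0
    return (o_a - e_a) ** 2 / v
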