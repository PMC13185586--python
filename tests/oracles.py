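"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive (plain Python loops, direct
enumeration) and shares no code with the implementation under test.
"""

from __future__ import annotations

import numpy as np


def brute_pileup(reads, length):
    """Per-column base counts from (start, end, {pos: base}) read tuples.

    Positions are 1-based inclusive; bases default to the reference, so the
    caller passes the full read bases instead: here ``reads`` items are
    (start, bases) with ``bases`` the literal sense-oriented string covering
    [start, start+len-1].
    """
    counts = {b: [0] * length for b in "ACGTN"}
    for start, bases in reads:
        for i, base in enumerate(bases):
            counts[base][start - 1 + i] += 1
    return counts


def brute_dedup_count(keys):
    """Distinct-key cardinality by explicit set construction."""
    seen = []
    for key in keys:
        if key not in seen:
            seen.append(key)
    return len(seen)


def brute_ks_statistic(x, y):
    """Maximal ECDF gap by evaluating both ECDFs on the pooled grid."""
    x = sorted(x)
    y = sorted(y)
    grid = sorted(set(x) | set(y))
    d = 0.0
    for g in grid:
        fx = sum(1 for v in x if v <= g) / len(x)
        fy = sum(1 for v in y if v <= g) / len(y)
        d = max(d, abs(fx - fy))
    return d


def brute_best_alignment(query, segments):
    """Best ungapped placement by scanning every offset on both strands.

    ``segments`` is an ordered list of (segment_id, sequence).  Returns
    (mismatches, segment_id, start0, strand) with ties resolved by segment
    order, then leftmost offset, then '+' strand; None if query longer than
    every segment.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = "".join(comp[b] for b in reversed(query))
    best = None
    for strand_rank, oriented in ((0, query), (1, rc)):
        for seg_idx, (sid, seq) in enumerate(segments):
            for start0 in range(len(seq) - len(oriented) + 1):
                mm = sum(
                    1
                    for a, b in zip(oriented, seq[start0 : start0 + len(oriented)])
                    if a != b
                )
                key = (mm, seg_idx, start0, strand_rank)
                if best is None or key < best[0]:
                    best = (key, sid, "+" if strand_rank == 0 else "-")
    if best is None:
        return None
    (mm, _, start0, _), sid, strand = best
    return mm, sid, start0, strand


def truncated_geometric_pmf(p_term, lo, hi):
    """PMF of a geometric(p_term) variable conditioned on lo <= L <= hi."""
    k = np.arange(lo, hi + 1, dtype=float)
    pmf = (1.0 - p_term) ** (k - 1) * p_term
    return k, pmf / pmf.sum()


def truncated_geometric_mean(p_term, lo, hi):
    k, pmf = truncated_geometric_pmf(p_term, lo, hi)
    return float((k * pmf).sum())


def truncated_geometric_var(p_term, lo, hi):
    k, pmf = truncated_geometric_pmf(p_term, lo, hi)
    mean = (k * pmf).sum()
    return float(((k - mean) ** 2 * pmf).sum())


def brute_spearman(x, y):
    """Spearman rho via explicit mid-ranking and Pearson on ranks."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            mid = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = mid
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den
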