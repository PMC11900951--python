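"""Independent brute-force oracles used only by the test suite.

These re-derive percentile ranks and equipercentile rank-matching with
plain Python loops and explicit segment scans, sharing no code with the
package's vectorised implementation.
"""

from __future__ import annotations


def brute_mid_rank(sample, x) -> float:
    """Mid-percentile rank by direct counting."""
    below = sum(1 for v in sample if v < x)
    equal = sum(1 for v in sample if v == x)
    return 100.0 * (below + 0.5 * equal) / len(sample)


def _nodes(sample, lo, hi):
    support = sorted(set(sample))
    xs = [lo - 0.5] + support + [hi + 0.5]
    rs = [0.0] + [brute_mid_rank(sample, s) for s in support] + [100.0]
    return xs, rs


def brute_forward(sample, lo, hi, x) -> float:
    """Continuized percentile rank via explicit segment scan."""
    xs, rs = _nodes(sample, lo, hi)
    if x <= xs[0]:
        return rs[0]
    for (x0, r0), (x1, r1) in zip(zip(xs, rs), zip(xs[1:], rs[1:])):
        if x0 <= x <= x1:
            return r0 + (r1 - r0) * (x - x0) / (x1 - x0)
    return rs[-1]


def brute_inverse(sample, lo, hi, r) -> float:
    """Score at rank r via explicit segment scan, clamped to [lo, hi]."""
    xs, rs = _nodes(sample, lo, hi)
    if r <= rs[0]:
        s = xs[0]
    elif r >= rs[-1]:
        s = xs[-1]
    else:
        s = xs[-1]
        for (x0, r0), (x1, r1) in zip(zip(xs, rs), zip(xs[1:], rs[1:])):
            if r0 <= r <= r1:
                s = x0 if r1 == r0 else x0 + (x1 - x0) * (r - r0) / (r1 - r0)
                break
    return min(max(s, lo), hi)


def brute_equipercentile(xs, ys, xrange, yrange):
    """Rank-matching table over the integer source grid, by brute force."""
    lo, hi = xrange
    out = {}
    for s in range(int(lo), int(hi) + 1):
        r = brute_forward(xs, lo, hi, s)
        out[s] = brute_inverse(ys, yrange[0], yrange[1], r)
    return out


def brute_spearman(xs, ys) -> float:
    """Rank correlation via average ranks and the Pearson formula, by loops."""

    def average_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = average_ranks(list(xs)), average_ranks(list(ys))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den
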