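"""Independent brute-force oracles used to validate the production code.

These are deliberately written as literal loops, separate from the
vectorized implementations in the package, so that agreement is a real
cross-check and not a tautology.
"""

from __future__ import annotations

import math

import numpy as np


def apen_bruteforce(x, m: int, r: float) -> float:
    """Approximate entropy by the O(N^2) double loop (self-matches included)."""
    x = list(map(float, x))
    n = len(x)

    def phi(mm: int) -> float:
        n_templates = n - mm + 1
        templates = [x[i : i + mm] for i in range(n_templates)]
        total = 0.0
        for a in templates:
            count = 0
            for b in templates:
                if max(abs(ai - bi) for ai, bi in zip(a, b)) <= r:
                    count += 1
            total += math.log(count / n_templates)
        return total / n_templates

    return phi(m) - phi(m + 1)


def rescaled_range_loops(x, d: int) -> tuple[float, int]:
    """Loop-literal mean rescaled range at segment length d.

    Splits the first M*d values (M = N // d) into adjacent segments; per
    segment the cumulative deviation from the segment mean is accumulated,
    its range divided by the segment sample SD (N-1 denominator), and the
    ratio averaged over segments with positive SD.
    """
    x = list(map(float, x))
    n_segments = len(x) // d
    ratios = []
    for m in range(n_segments):
        seg = x[m * d : (m + 1) * d]
        e_m = sum(seg) / d
        s_m = math.sqrt(sum((v - e_m) ** 2 for v in seg) / (d - 1))
        if s_m == 0:
            continue
        acc, dev = 0.0, []
        for v in seg:
            acc += v - e_m
            dev.append(acc)
        r_m = max(dev) - min(dev)
        ratios.append(r_m / s_m)
    if not ratios:
        raise ValueError("all segments degenerate")
    return sum(ratios) / len(ratios), len(ratios)


def window_counts_bruteforce(timestamps, T: float, duration: float) -> list[int]:
    """Spike counts per complete window by direct interval membership.

    Windows are [i*T, (i+1)*T) anchored at 0, with the same relative edge
    tolerance convention as the implementation (a spike within 1e-9*T below
    an edge belongs to the upper window).
    """
    n = int(math.floor(duration / T))
    counts = []
    for i in range(n):
        lo = i * T - 1e-9 * T
        hi = (i + 1) * T - 1e-9 * T
        counts.append(sum(1 for t in timestamps if lo <= t < hi))
    return counts


def paired_t_hand(baseline, stim) -> float:
    """Paired t statistic d_bar / (s_d / sqrt(n)) with d = stim - baseline."""
    diffs = [s - b for s, b in zip(stim, baseline)]
    n = len(diffs)
    d_bar = sum(diffs) / n
    s_d = math.sqrt(sum((d - d_bar) ** 2 for d in diffs) / (n - 1))
    return d_bar / (s_d / math.sqrt(n))


def anis_lloyd_expected_rs(d: int) -> float:
    """Closed-form expectation of (R/S)_d for an i.i.d. sequence
    (Anis-Lloyd with the small-d finite-sample correction factor)."""
    from scipy.special import gammaln

    front = (d - 0.5) / d
    ratio = math.exp(gammaln((d - 1) / 2) - gammaln(d / 2)) / math.sqrt(math.pi)
    s = sum(math.sqrt((d - i) / i) for i in range(1, d))
    return front * ratio * s


def fgn_autocov_closed_form(k: int, H: float) -> float:
    """gamma(k) = 0.5(|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H})."""
    return 0.5 * (
        abs(k + 1) ** (2 * H) - 2 * abs(k) ** (2 * H) + abs(k - 1) ** (2 * H)
    )
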