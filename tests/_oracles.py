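"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's windowed/streaming evaluation paths:
profiles are built by evaluating every kernel term at every grid point,
normative profiles by explicit list averaging, and correlations from the
textbook sum formulas. Slow but transparently correct on small instances.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_profile(
    presses, duration, bandwidth=1.0, truncation_radius=3.0, sampling_rate=10.0
):
    """Naive full evaluation of the clipped Gaussian-sum boundary profile.

    Every kernel term is evaluated at every grid point; terms at or beyond
    the truncation radius contribute exactly zero (part of the kernel
    definition, shared with the implementation).
    """
    n = int(math.floor(duration * sampling_rate)) + 1
    times = [k / sampling_rate for k in range(n)]
    values = []
    radius = truncation_radius * bandwidth
    for t in times:
        total = 0.0
        for p in presses:
            if abs(t - p) < radius:
                total += math.exp(-((t - p) ** 2) / (2.0 * bandwidth**2))
        values.append(min(1.0, total))
    return np.asarray(times), np.asarray(values)


def brute_force_loo_agreement(
    owner_id,
    owner_presses,
    reference,  # dict id -> presses (the reference group's post-test logs)
    duration,
    bandwidth=1.0,
    truncation_radius=3.0,
    sampling_rate=10.0,
):
    """Leave-one-out agreement from first principles; None when undefined."""
    _, owner_values = brute_force_profile(
        owner_presses, duration, bandwidth, truncation_radius, sampling_rate
    )
    included = [
        brute_force_profile(p, duration, bandwidth, truncation_radius, sampling_rate)[1]
        for pid, p in reference.items()
        if pid != owner_id
    ]
    if not included:
        raise ValueError("empty reference after exclusion")
    norm = np.sum(included, axis=0) / len(included)
    return pearson_sum_formula(owner_values, norm)


def pearson_sum_formula(x, y):
    """Pearson r via the raw sum formula; None for zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx = x.sum()
    sy = y.sum()
    sxx = (x * x).sum()
    syy = (y * y).sum()
    sxy = (x * y).sum()
    vx = sxx - sx * sx / n
    vy = syy - sy * sy / n
    if vx <= 0 or vy <= 0:
        return None
    return (sxy - sx * sy / n) / math.sqrt(vx * vy)


def kappa_from_table(a, b):
    """Cohen's kappa from the explicit 2x2 contingency table."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = a.size
    n11 = int(np.sum((a == 1) & (b == 1)))
    n10 = int(np.sum((a == 1) & (b == 0)))
    n01 = int(np.sum((a == 0) & (b == 1)))
    n00 = int(np.sum((a == 0) & (b == 0)))
    po = (n11 + n00) / n
    pe = ((n11 + n10) / n) * ((n11 + n01) / n) + ((n01 + n00) / n) * ((n10 + n00) / n)
    if pe == 1.0:
        return None
    return (po - pe) / (1.0 - pe)
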