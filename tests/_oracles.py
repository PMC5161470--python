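"""Independent reference implementations used only as test oracles.

These deliberately avoid the code paths of the package: plug-in estimators
work from Counter-based contingency tables, the B-spline basis is evaluated
with the textbook Cox-de Boor recursion, and coverage is enumerated with
plain tuples.
"""

from collections import Counter
from math import log2

import numpy as np


def plugin_entropy(x) -> float:
    """Histogram plug-in entropy in bits."""
    n = len(x)
    return -sum(c / n * log2(c / n) for c in Counter(x).values())


def plugin_mi(x, y) -> float:
    """Contingency-table plug-in mutual information in bits."""
    n = len(x)
    cx, cy = Counter(x), Counter(y)
    cxy = Counter(zip(x, y))
    return sum(
        c / n * log2(c * n / (cx[a] * cy[b])) for (a, b), c in cxy.items()
    )


def deboor_basis(x: float, knots, degree: int, i: int) -> float:
    """Cox-de Boor recursion for the i-th B-spline basis of given degree."""
    if degree == 0:
        # half-open intervals; the last nonempty interval is closed on the right
        if knots[i] <= x < knots[i + 1]:
            return 1.0
        if x == knots[-1] and knots[i] < knots[i + 1] == knots[-1]:
            return 1.0
        return 0.0
    left = 0.0
    if knots[i + degree] > knots[i]:
        left = (x - knots[i]) / (knots[i + degree] - knots[i]) * deboor_basis(
            x, knots, degree - 1, i
        )
    right = 0.0
    if knots[i + degree + 1] > knots[i + 1]:
        right = (knots[i + degree + 1] - x) / (
            knots[i + degree + 1] - knots[i + 1]
        ) * deboor_basis(x, knots, degree - 1, i + 1)
    return left + right


def coverage_oracle(values: np.ndarray, tags) -> tuple[float, int, list[int]]:
    """Direct enumeration of pattern groups and full-sequence multiplicities."""
    n_samples = values.shape[1]
    groups: dict[tuple, list[int]] = {}
    for p in range(n_samples):
        key = tuple(values[t, p] for t in tags)
        groups.setdefault(key, []).append(p)
    g_counts = []
    for members in groups.values():
        seqs = Counter(tuple(values[:, p]) for p in members)
        g_counts.append(max(seqs.values()))
    return sum(g_counts) / n_samples, len(groups), g_counts


def contingency_tables(total: int):
    """All 3x3 nonnegative integer matrices with the given total count."""
    from itertools import product

    for flat in product(range(total + 1), repeat=8):
        s = sum(flat)
        if s <= total:
            yield np.array(flat + (total - s,), dtype=int).reshape(3, 3)


def table_to_vectors(table: np.ndarray) -> tuple[list, list]:
    """Materialize a joint count table as a pair of tri-level vectors."""
    xs, ys = [], []
    for a in range(3):
        for b in range(3):
            xs.extend([a] * int(table[a, b]))
            ys.extend([b] * int(table[a, b]))
    return xs, ys
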