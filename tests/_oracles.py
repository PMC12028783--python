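"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately written as plain-Python, step-by-step transcriptions
of the textbook definitions (loops, no vectorization, no reuse of package
code) so that agreement with the package is a genuine two-route check.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

from scipy.stats import studentized_range

# quantiles are expensive to evaluate; memoize per (alpha, span, df)
_Q_CACHE: dict[tuple[float, int, int], float] = {}


def _q(alpha: float, span: int, df: int) -> float:
    key = (alpha, span, df)
    if key not in _Q_CACHE:
        _Q_CACHE[key] = float(
            studentized_range.ppf((1.0 - alpha) ** (span - 1), span, df)
        )
    return _Q_CACHE[key]


def entropy_weights_oracle(matrix: Sequence[Sequence[float]]) -> list[float]:
    """Entropy weight method, computed cell by cell from the definition."""
    m = len(matrix)
    n = len(matrix[0])
    weights_raw = []
    for j in range(n):
        col_sum = sum(matrix[i][j] for i in range(m))
        entropy = 0.0
        for i in range(m):
            p = matrix[i][j] / col_sum
            if p > 0:
                entropy += p * math.log(p)
        entropy = -entropy / math.log(m)
        weights_raw.append(1.0 - entropy)
    # a constant column has p = 1/m everywhere; roundoff may leave a tiny
    # residual divergence, which the definition says is exactly zero
    for j in range(n):
        if len({matrix[i][j] for i in range(m)}) == 1:
            weights_raw[j] = 0.0
    total = sum(weights_raw)
    return [w / total for w in weights_raw]


def topsis_oracle(
    matrix: Sequence[Sequence[float]],
    weights: Sequence[float],
    benefit: Sequence[bool] | None = None,
) -> list[float]:
    """Classical TOPSIS closeness with vector normalization, loop by loop."""
    m = len(matrix)
    n = len(matrix[0])
    if benefit is None:
        benefit = [True] * n

    norms = [math.sqrt(sum(matrix[i][j] ** 2 for i in range(m))) for j in range(n)]
    V = [[weights[j] * matrix[i][j] / norms[j] for j in range(n)] for i in range(m)]

    ideal, anti = [], []
    for j in range(n):
        col = [V[i][j] for i in range(m)]
        ideal.append(max(col) if benefit[j] else min(col))
        anti.append(min(col) if benefit[j] else max(col))

    closeness = []
    for i in range(m):
        d_plus = math.sqrt(sum((V[i][j] - ideal[j]) ** 2 for j in range(n)))
        d_minus = math.sqrt(sum((V[i][j] - anti[j]) ** 2 for j in range(n)))
        closeness.append(d_minus / (d_plus + d_minus) if d_plus + d_minus > 0 else 0.5)
    return closeness


def duncan_oracle(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> dict[str, str]:
    """Duncan letter display by exhaustively testing every span.

    Enumerates all spans of the descending mean order, marks each span
    non-significant iff its end-point gap is within the least significant
    range for its length, keeps the maximal non-significant spans, and
    letters them left to right.
    """
    labels = list(groups)
    data = {g: [float(v) for v in groups[g]] for g in labels}
    k = len(labels)
    ns = {g: len(v) for g, v in data.items()}
    means = {g: sum(v) / len(v) for g, v in data.items()}
    big_n = sum(ns.values())
    df = big_n - k
    sse = sum(sum((x - means[g]) ** 2 for x in data[g]) for g in labels)
    mse = sse / df
    n_h = k / sum(1.0 / ns[g] for g in labels)

    order = sorted(range(k), key=lambda i: (-means[labels[i]], i))
    sorted_labels = [labels[i] for i in order]
    sorted_means = [means[g] for g in sorted_labels]

    def lsr(span: int) -> float:
        return _q(alpha, span, df) * math.sqrt(mse / n_h)

    nonsig_spans = []
    for i in range(k):
        for j in range(i, k):
            if i == j or sorted_means[i] - sorted_means[j] <= lsr(j - i + 1):
                nonsig_spans.append((i, j))

    maximal = [
        (i, j)
        for (i, j) in nonsig_spans
        if not any(a <= i and j <= b and (a, b) != (i, j) for (a, b) in nonsig_spans)
    ]
    maximal.sort()

    letters = {g: "" for g in sorted_labels}
    for idx, (i, j) in enumerate(maximal):
        for pos in range(i, j + 1):
            letters[sorted_labels[pos]] += "abcdefghijklmnopqrstuvwxyz"[idx]
    return letters
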