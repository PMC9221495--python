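"""Independent brute-force DTW oracle used by the tests.

Enumerates every monotone, stepwise-contiguous warping path from (0, 0) to
(n-1, m-1) (steps: right, down, diagonal) and minimizes the summed local
cost along the path.  Exponential in the sequence lengths, so only usable
for short sequences (<= ~7 samples) — which is the point: it shares no code
or algorithmic idea with the dynamic-programming implementation it checks.
"""

from __future__ import annotations


def local_cost(a: float, b: float, kind: str) -> float:
    return abs(a - b) if kind == "absolute" else (a - b) ** 2


def dtw_brute_force(x, y, kind: str = "absolute") -> float:
    """Minimum path cost by exhaustive enumeration of warping paths."""
    n, m = len(x), len(y)
    best = [float("inf")]

    def walk(i: int, j: int, acc: float) -> None:
        acc += local_cost(x[i], y[j], kind)
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc)
        if i + 1 < n:
            walk(i + 1, j, acc)
        if j + 1 < m:
            walk(i, j + 1, acc)

    walk(0, 0, 0.0)
    return best[0]
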