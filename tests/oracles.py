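"""Independent oracles used only by the test suite.

The incidence-matrix ladder solver below deliberately shares nothing with
the package's nodal (Laplacian) solver: it builds the full mixed system in
pressures *and* edge flows — one Ohm's-law row per edge, one conservation
row per node, one gauge row — and solves it as a single square linear
system.  Agreement between the two routes is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np


def dense_ladder_ratios(
    rung_resistances,
    supply_resistances,
    collector_resistances,
    configuration: str = "counter_current",
) -> np.ndarray:
    """Fractional flow ratios Q_i/Q_P via a dense incidence-matrix solve."""
    n = len(rung_resistances)
    # node indices: s_i -> i, c_i -> n + i   (0-based)
    edges: list[tuple[int, int, float]] = []
    for i in range(n):
        edges.append((i, n + i, float(rung_resistances[i])))
    for i in range(n - 1):
        edges.append((i, i + 1, float(supply_resistances[i])))
        edges.append((n + i, n + i + 1, float(collector_resistances[i])))
    m = len(edges)
    n_nodes = 2 * n
    inlet = 0
    outlet = n if configuration == "counter_current" else 2 * n - 1

    # unknowns: [p_0 .. p_{2n-1}, f_0 .. f_{m-1}]
    a = np.zeros((n_nodes + m, n_nodes + m))
    b = np.zeros(n_nodes + m)
    row = 0
    for e, (u, v, r) in enumerate(edges):  # Ohm's law per edge
        a[row, u] = 1.0
        a[row, v] = -1.0
        a[row, n_nodes + e] = -r
        row += 1
    for node in range(n_nodes):           # conservation per non-outlet node
        if node == outlet:
            continue
        for e, (u, v, _) in enumerate(edges):
            if u == node:
                a[row, n_nodes + e] += 1.0
            elif v == node:
                a[row, n_nodes + e] -= 1.0
        b[row] = 1.0 if node == inlet else 0.0
        row += 1
    a[row, outlet] = 1.0                  # gauge: p_outlet = 0
    row += 1
    assert row == n_nodes + m
    x = np.linalg.solve(a, b)
    flows = x[n_nodes:]
    return flows[:n]                      # rung edges first, oriented s->c; Q_P = 1


def bisect_root(f, lo: float, hi: float, iterations: int = 100) -> float:
    """Plain bisection root finder (used as an oracle for separating fractions)."""
    flo = f(lo)
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        if (f(mid) > 0) == (flo > 0):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
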