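"""Incremental union-find kernel for fragmentation-entropy curves.

The curve is computed by processing the removal order in *reverse*:
starting from the fully fragmented state (all nodes isolated) nodes are
re-activated one by one, merging components with a weighted union-find
while maintaining ``T = sum_i n_i * ln(n_i)`` over current components.
The normalized fragmentation entropy is then

    S = 1 - T / (N * ln N)

(equivalent to -(1/ln N) * sum p_i ln p_i with p_i = n_i / N), so one
full curve costs O((N + E) * alpha(N)).

The hot loop is numba-jitted when numba is importable; a pure-Python
twin with identical semantics is kept as a fallback and for
environments where JIT compilation is undesirable.
"""

from __future__ import annotations

import math

import numpy as np


def _entropy_curve_py(indptr, indices, order, n):
    parent = np.arange(n, dtype=np.int64)
    size = np.ones(n, dtype=np.int64)
    active = np.zeros(n, dtype=np.bool_)
    s_vals = np.empty(n + 1, dtype=np.float64)
    log_n = math.log(n)
    norm = n * log_n
    t = 0.0
    s_vals[n] = 1.0
    for j in range(n):
        v = order[n - 1 - j]
        active[v] = True
        for k in range(indptr[v], indptr[v + 1]):
            u = indices[k]
            if not active[u]:
                continue
            # find roots with path halving
            ra = v
            while parent[ra] != ra:
                parent[ra] = parent[parent[ra]]
                ra = parent[ra]
            rb = u
            while parent[rb] != rb:
                parent[rb] = parent[parent[rb]]
                rb = parent[rb]
            if ra == rb:
                continue
            na, nb = size[ra], size[rb]
            if na < nb:
                ra, rb = rb, ra
                na, nb = nb, na
            parent[rb] = ra
            size[ra] = na + nb
            t += ((na + nb) * math.log(na + nb)
                  - (na * math.log(na) if na > 1 else 0.0)
                  - (nb * math.log(nb) if nb > 1 else 0.0))
        s_vals[n - 1 - j] = 1.0 - t / norm
    return s_vals


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _entropy_curve = njit(cache=True)(_entropy_curve_py)
except ImportError:  # pragma: no cover
    _entropy_curve = _entropy_curve_py


def entropy_curve(indptr, indices, order, n: int) -> np.ndarray:
    """S values at k = 0..N removals for the given full removal order.

    ``order[k]`` is the node index isolated at step k+1; S[k] is the
    normalized fragmentation entropy after k isolations (S[0] is the
    intact network, S[N] = 1).
    """
    if n < 2:
        raise ValueError("entropy undefined for N < 2")
    order = np.ascontiguousarray(order, dtype=np.int64)
    if order.shape[0] != n:
        raise ValueError("order must cover every node exactly once")
    return _entropy_curve(indptr, indices, order, n)
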