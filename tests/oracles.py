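"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (explicit loops, normal equations,
transitive closure) kept free of any code path from the package itself.
"""

import numpy as np
from scipy import stats


def rank_avg(v):
    v = np.asarray(v, float)
    return np.array([np.sum(v < vi) + (np.sum(v == vi) + 1) / 2.0 for vi in v])


def rank_regress_oracle(x, y, z):
    """Partial Spearman via explicit rank regression (least squares)."""
    rx, ry, rz = rank_avg(x), rank_avg(y), rank_avg(z)
    n = rx.size
    Z = np.column_stack([np.ones(n), rz])
    bx = np.linalg.lstsq(Z, rx, rcond=None)[0]
    by = np.linalg.lstsq(Z, ry, rcond=None)[0]
    ex, ey = rx - Z @ bx, ry - Z @ by
    rho = float(ex @ ey / np.sqrt((ex @ ex) * (ey @ ey)))
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 3) / (1 - rho**2))
    return rho, float(2 * stats.t.sf(abs(t), n - 3))


def components_oracle(cells, spatial_edges):
    """Transitive-closure components on explicit (node, step) cells."""
    cells = sorted(cells)
    n = len(cells)
    adj = np.eye(n, dtype=bool)
    eset = {tuple(e) for e in spatial_edges} | {
        tuple(e[::-1]) for e in spatial_edges
    }
    for i, (v1, s1) in enumerate(cells):
        for j, (v2, s2) in enumerate(cells):
            if i >= j:
                continue
            if (s1 == s2 and (v1, v2) in eset) or (v1 == v2 and abs(s1 - s2) == 1):
                adj[i, j] = adj[j, i] = True
    while True:
        nxt = adj | (adj @ adj)
        if np.array_equal(nxt, adj):
            break
        adj = nxt
    comps, seen = [], set()
    for i in range(n):
        if i in seen:
            continue
        idx = np.flatnonzero(adj[i])
        seen.update(idx.tolist())
        comps.append(frozenset(cells[j] for j in idx))
    return set(comps)


def brute_max_mass(values, y, z, edges, alpha, min_steps):
    """Mini-pipeline: cell rho/p, run filter, flood fill, max |cluster mass|."""
    n, nv, ns = values.shape
    rho = np.zeros((nv, ns))
    sig = np.zeros((nv, ns), bool)
    for v in range(nv):
        for s in range(ns):
            r, p = rank_regress_oracle(values[:, v, s], y, z)
            rho[v, s] = r
            sig[v, s] = p < alpha
    best = 0.0
    eset = {tuple(e) for e in edges} | {tuple(e[::-1]) for e in edges}
    for sign in (1, -1):
        mask = sig & ((rho > 0) if sign > 0 else (rho < 0))
        keep = np.zeros_like(mask)
        for v in range(nv):
            s = 0
            while s < ns:
                if mask[v, s]:
                    e = s
                    while e + 1 < ns and mask[v, e + 1]:
                        e += 1
                    if e - s + 1 >= min_steps:
                        keep[v, s : e + 1] = True
                    s = e + 1
                else:
                    s += 1
        cells = set(zip(*np.nonzero(keep)))
        while cells:
            comp = {cells.pop()}
            grew = True
            while grew:
                grew = False
                for c in list(cells):
                    for m in comp:
                        if (c[1] == m[1] and (c[0], m[0]) in eset) or (
                            c[0] == m[0] and abs(c[1] - m[1]) == 1
                        ):
                            comp.add(c)
                            cells.discard(c)
                            grew = True
                            break
            best = max(best, abs(sum(rho[c] for c in comp)))
    return best
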