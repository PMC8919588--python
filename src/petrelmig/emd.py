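"""Earth mover's distance between spatial point distributions.

EMD here is the optimal-transport cost between two weighted point sets with
great-circle (Haversine, sphere radius 6371 km) ground distance: the minimal
total "effort" (probability mass × kilometres) needed to morph one
distribution into the other. Unlike overlap indices it grades dissimilarity
of non-overlapping distributions by how far apart they are, starting at zero
for identical migrations.

The transportation problem is solved *exactly* by a primal transportation
simplex (cycle pivoting with incremental dual updates and block pricing),
JIT-compiled with numba so that all-pairs matrices over hundreds of tracks
are tractable. Two fast paths: equal-size uniform sets reduce to the linear
assignment problem; tiny instances and any solver failure fall back to
``scipy.optimize.linprog``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km (broadcasting over array inputs)."""
    lon1, lat1, lon2, lat2 = (np.asarray(x, dtype=float) for x in (lon1, lat1, lon2, lat2))
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dphi = p2 - p1
    dlmb = np.deg2rad(lon2 - lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(np.sqrt(a), 1.0))


def haversine_matrix(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Pairwise great-circle distances, shape (len(set1), len(set2))."""
    return haversine_km(
        np.asarray(lon1, dtype=float)[:, None],
        np.asarray(lat1, dtype=float)[:, None],
        np.asarray(lon2, dtype=float)[None, :],
        np.asarray(lat2, dtype=float)[None, :],
    )


@njit(cache=True)
def _transport_simplex(C, a, b):  # pragma: no cover - exercised via emd()
    """Exact transportation simplex. Returns (status, optimal cost).

    status 0 = optimal, 1 = iteration limit (caller falls back to an LP).
    Basis kept as a spanning tree over n source + m sink nodes in adjacency
    lists; duals updated incrementally on the smaller cut side; entering arc
    chosen by block search over reduced costs.
    """
    n = C.shape[0]
    m = C.shape[1]
    N = n + m
    # --- initial basic feasible solution: north-west corner rule ------------
    max_basis = N  # n+m-1 cells + 1 slack for the entering arc during a pivot
    brow = np.empty(max_basis, np.int64)
    bcol = np.empty(max_basis, np.int64)
    bflow = np.empty(max_basis, np.float64)
    ra = a.copy()
    rb = b.copy()
    i = 0
    j = 0
    nb = 0
    while i < n and j < m:
        q = min(ra[i], rb[j])
        brow[nb] = i
        bcol[nb] = j
        bflow[nb] = q
        nb += 1
        ra[i] -= q
        rb[j] -= q
        if i == n - 1 and j == m - 1:
            break
        if ra[i] <= rb[j] and i < n - 1:
            i += 1
        elif j < m - 1:
            j += 1
        else:
            i += 1
    # nb == n + m - 1 by construction of NW corner

    # --- adjacency lists over tree nodes (0..n-1 rows, n..N-1 cols) ---------
    cap = 2 * max_basis
    head = np.full(N, -1, np.int64)
    nxt = np.full(cap, -1, np.int64)
    prv = np.full(cap, -1, np.int64)
    to = np.empty(cap, np.int64)
    eidx = np.empty(cap, np.int64)  # adjacency entry -> basis index

    def _add_entry(node, entry, other, k):
        to[entry] = other
        eidx[entry] = k
        nxt[entry] = head[node]
        prv[entry] = -1
        if head[node] != -1:
            prv[head[node]] = entry
        head[node] = entry

    for k in range(nb):
        _add_entry(brow[k], 2 * k, n + bcol[k], k)
        _add_entry(n + bcol[k], 2 * k + 1, brow[k], k)

    # --- duals from the tree ------------------------------------------------
    u = np.zeros(n, np.float64)
    v = np.zeros(m, np.float64)
    seen = np.zeros(N, np.uint8)
    stack = np.empty(N, np.int64)
    top = 0
    stack[top] = 0
    top += 1
    seen[0] = 1
    u[0] = 0.0
    while top > 0:
        top -= 1
        node = stack[top]
        e = head[node]
        while e != -1:
            o = to[e]
            if seen[o] == 0:
                seen[o] = 1
                k = eidx[e]
                if o >= n:
                    v[o - n] = C[brow[k], bcol[k]] - u[brow[k]]
                else:
                    u[o] = C[brow[k], bcol[k]] - v[bcol[k]]
                stack[top] = o
                top += 1
            e = nxt[e]

    nm = n * m
    block = 1024
    if block > nm:
        block = nm
    cursor = 0
    parent_node = np.empty(N, np.int64)
    parent_entry = np.empty(N, np.int64)
    path_cells = np.empty(N, np.int64)
    max_iter = 100 * N + 10000
    tol = 1e-11

    for _it in range(max_iter):
        # --- entering arc: block search over reduced costs ------------------
        best = -tol
        best_flat = -1
        scanned = 0
        while scanned < nm:
            end = cursor + block
            for f in range(cursor, end):
                ff = f if f < nm else f - nm
                r = C[ff // m, ff % m] - u[ff // m] - v[ff % m]
                if r < best:
                    best = r
                    best_flat = ff
            cursor = end if end < nm else end - nm
            scanned += block
            if best_flat >= 0:
                break
        if best_flat < 0:
            total = 0.0
            for k in range(nb):
                total += bflow[k] * C[brow[k], bcol[k]]
            return 0, total
        ei = best_flat // m
        ej = best_flat % m
        rcost = best

        # --- cycle: tree path from row node ei to col node n+ej -------------
        src = ei
        dst = n + ej
        for q in range(N):
            seen[q] = 0
        top = 0
        stack[top] = src
        top += 1
        seen[src] = 1
        parent_node[src] = -1
        parent_entry[src] = -1
        while top > 0:
            top -= 1
            node = stack[top]
            if node == dst:
                break
            e = head[node]
            while e != -1:
                o = to[e]
                if seen[o] == 0:
                    seen[o] = 1
                    parent_node[o] = node
                    parent_entry[o] = e
                    stack[top] = o
                    top += 1
                e = nxt[e]
        # walk back dst -> src collecting basis cells
        plen = 0
        node = dst
        while node != src:
            path_cells[plen] = eidx[parent_entry[node]]
            plen += 1
            node = parent_node[node]
        # signs: path_cells[0] adjacent to dst (col of entering arc) gets -1,
        # then alternate; entering arc itself is +1.
        theta = 1.0e300
        leave_pos = -1
        for p in range(plen):
            if p % 2 == 0:  # minus cells
                k = path_cells[p]
                if bflow[k] < theta:
                    theta = bflow[k]
                    leave_pos = p
        leave_k = path_cells[leave_pos]
        # --- update flows ----------------------------------------------------
        for p in range(plen):
            k = path_cells[p]
            if p % 2 == 0:
                bflow[k] -= theta
            else:
                bflow[k] += theta

        lrow = brow[leave_k]
        lcol = bcol[leave_k]
        # remove leaving arc entries (2*leave_k, 2*leave_k+1)
        for t in range(2):
            e = 2 * leave_k + t
            node = lrow if t == 0 else n + lcol
            if prv[e] == -1:
                head[node] = nxt[e]
            else:
                nxt[prv[e]] = nxt[e]
            if nxt[e] != -1:
                prv[nxt[e]] = prv[e]
        # --- dual update on the component containing the entering col node --
        # after the cut, shift potentials in the piece containing n+ej:
        # v += rcost for cols, u -= rcost for rows
        for q in range(N):
            seen[q] = 0
        top = 0
        stack[top] = n + ej
        top += 1
        seen[n + ej] = 1
        v[ej] += rcost
        while top > 0:
            top -= 1
            node = stack[top]
            e = head[node]
            while e != -1:
                o = to[e]
                if seen[o] == 0:
                    seen[o] = 1
                    if o >= n:
                        v[o - n] += rcost
                    else:
                        u[o] -= rcost
                    stack[top] = o
                    top += 1
                e = nxt[e]
        # install entering arc in the leaving slot
        brow[leave_k] = ei
        bcol[leave_k] = ej
        bflow[leave_k] = theta
        _add_entry(ei, 2 * leave_k, n + ej, leave_k)
        _add_entry(n + ej, 2 * leave_k + 1, ei, leave_k)

    return 1, 0.0


def transport_cost(C: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Exact minimum transportation cost for cost matrix C, marginals a, b."""
    C = np.ascontiguousarray(C, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if C.shape != (len(a), len(b)):
        raise ValueError("cost matrix shape does not match marginals")
    if abs(a.sum() - b.sum()) > 1e-9:
        raise ValueError(f"marginals must balance: {a.sum()} vs {b.sum()}")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("marginals must be non-negative")
    status, cost = _transport_simplex(C, a, b)
    if status != 0:
        return _linprog_transport(C, a, b)
    return cost


def _linprog_transport(C, a, b) -> float:
    from scipy.optimize import linprog
    from scipy.sparse import csr_matrix

    n, m = C.shape
    rows = np.concatenate([np.repeat(np.arange(n), m), n + np.tile(np.arange(m), n)])
    cols = np.concatenate([np.arange(n * m), np.arange(n * m)])
    A = csr_matrix((np.ones(2 * n * m), (rows, cols)), shape=(n + m, n * m))
    res = linprog(C.ravel(), A_eq=A, b_eq=np.concatenate([a, b]), method="highs")
    if not res.success:
        raise RuntimeError(f"transportation LP failed: {res.message}")
    return float(res.fun)


class PointSet:
    """Weighted lon/lat point set (uniform weights by default)."""

    def __init__(self, lon, lat, weights=None):
        self.lon = np.atleast_1d(np.asarray(lon, dtype=float))
        self.lat = np.atleast_1d(np.asarray(lat, dtype=float))
        if len(self.lon) != len(self.lat) or len(self.lon) == 0:
            raise ValueError("point set needs >= 1 (lon, lat) pair")
        if weights is None:
            weights = np.full(len(self.lon), 1.0 / len(self.lon))
        self.weights = np.asarray(weights, dtype=float)
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")

    def __len__(self) -> int:
        return len(self.lon)


def emd(A: PointSet, B: PointSet) -> float:
    """Earth mover's distance (km) between two point sets, Haversine ground cost."""
    C = haversine_matrix(A.lon, A.lat, B.lon, B.lat)
    nA, nB = len(A), len(B)
    uniform = (
        np.allclose(A.weights, 1.0 / nA, atol=1e-12)
        and np.allclose(B.weights, 1.0 / nB, atol=1e-12)
    )
    if nA == 1 or nB == 1:
        # transport forced through the singleton: cost is the weighted mean distance
        return float(A.weights @ C @ B.weights)
    if uniform and nA == nB:
        from scipy.optimize import linear_sum_assignment

        r, c = linear_sum_assignment(C)
        return float(C[r, c].sum() / nA)
    return transport_cost(C, A.weights, B.weights)
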