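"""Independent brute-force reference implementations for the test suite.

Everything here is written with plain Python loops and explicit formulas —
no code shared with the package — so it can serve as an oracle for the
pipeline's partition function, mass exponent, spectrum and dimension curves.
"""

import math

INF = float("inf")


def floyd_warshall(n, edges, weighted=False):
    """Dense all-pairs shortest paths from an edge list of index pairs."""
    dist = [[0.0 if i == j else INF for j in range(n)] for i in range(n)]
    for e in edges:
        if weighted:
            i, j, w = e
        else:
            (i, j), w = e, 1.0
        if w < dist[i][j]:
            dist[i][j] = w
            dist[j][i] = w
    for k in range(n):
        dk = dist[k]
        for i in range(n):
            dik = dist[i][k]
            if dik == INF:
                continue
            di = dist[i]
            for j in range(n):
                alt = dik + dk[j]
                if alt < di[j]:
                    di[j] = alt
    return dist


def slope_r2(xs, ys):
    """Least-squares slope and R^2 via explicit sums."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    slope = sxy / sxx
    ss_res = sum((y - my - slope * (x - mx)) ** 2 for x, y in zip(xs, ys))
    ss_tot = sum((y - my) ** 2 for y in ys)
    r2 = 1.0 if ss_tot < 1e-12 else 1.0 - ss_res / ss_tot
    return slope, max(0.0, min(1.0, r2))


def brute_force_nmfa(dist, q_values, fit_fraction=0.9, min_fit_scales=3):
    """Straight-loop partition function, mass exponent, spectrum, dimension.

    ``dist`` is a dense all-pairs distance list-of-lists of a connected
    unweighted graph.  Returns a dict of lists keyed by U, tau, alpha, f, D,
    plus the radii used.
    """
    n = len(dist)
    d = max(max(row) for row in dist)
    r_start = max(
        min(dist[i][j] for j in range(n) if j != i) for i in range(n)
    )
    radii = [float(r) for r in range(int(math.ceil(r_start)), int(d) + 1)]

    # box masses, center excluded
    masses = []
    for i in range(n):
        row = []
        for r in radii:
            m = 0
            for j in range(n):
                if j != i and dist[i][j] <= r + 1e-12:
                    m += 1
            row.append(m)
        masses.append(row)

    U = []
    for q in q_values:
        row = []
        for k in range(len(radii)):
            s = 0.0
            for i in range(n):
                u = masses[i][k] / n
                s += u**q
            row.append(s)
        U.append(row)

    fit_idx = [k for k, r in enumerate(radii) if r <= fit_fraction * d + 1e-12]
    if len(fit_idx) < min_fit_scales:
        fit_idx = list(range(min_fit_scales))
    xs = [math.log(radii[k] / d) for k in fit_idx]
    tau = []
    for qi in range(len(q_values)):
        ys = [math.log(U[qi][k]) for k in fit_idx]
        tau.append(slope_r2(xs, ys)[0])

    # central differences inside, one-sided first order at the ends
    q = list(q_values)
    alpha = []
    for i in range(len(q)):
        if i == 0:
            alpha.append((tau[1] - tau[0]) / (q[1] - q[0]))
        elif i == len(q) - 1:
            alpha.append((tau[-1] - tau[-2]) / (q[-1] - q[-2]))
        else:
            alpha.append((tau[i + 1] - tau[i - 1]) / (q[i + 1] - q[i - 1]))
    f = [q[i] * alpha[i] - tau[i] for i in range(len(q))]
    D = []
    for i in range(len(q)):
        if abs(q[i]) < 1e-12:
            D.append(alpha[i])
        else:
            D.append(tau[i] / q[i])
    return {"radii": radii, "masses": masses, "U": U, "tau": tau,
            "alpha": alpha, "f": f, "D": D}


def random_connected_graph(rng, n_max=30):
    """Random connected simple graph as (n, edge index pairs)."""
    n = int(rng.integers(4, n_max + 1))
    # random spanning tree guarantees connectivity
    edges = set()
    for v in range(1, n):
        u = int(rng.integers(0, v))
        edges.add((u, v))
    n_extra = int(rng.integers(0, 2 * n))
    for _ in range(n_extra):
        u = int(rng.integers(0, n))
        v = int(rng.integers(0, n))
        if u != v:
            edges.add((min(u, v), max(u, v)))
    return n, sorted(edges)
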