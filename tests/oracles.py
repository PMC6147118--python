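"""Independent brute-force reference implementations used by the tests.

Everything here is written with explicit loops against the definitions,
kept deliberately separate from the package's vectorized code paths.
"""

import math


def strength_oracle(M, side):
    P, A = len(M), len(M[0])
    row_tot = [sum(M[i]) for i in range(P)]
    col_tot = [sum(M[i][j] for i in range(P)) for j in range(A)]
    if side == "bee":
        return [sum(M[i][j] / row_tot[i] for i in range(P)) for j in range(A)]
    return [sum(M[i][j] / col_tot[j] for j in range(A)) for i in range(P)]


def cq_oracle(M):
    P, A = len(M), len(M[0])
    m = sum(sum(row) for row in M)
    total = 0.0
    for i in range(P):
        t = sum(M[i])
        h = -sum((x / t) * math.log2(x / t) for x in M[i] if x > 0)
        total += t * 2.0**h
    for j in range(A):
        col = [M[i][j] for i in range(P)]
        t = sum(col)
        h = -sum((x / t) * math.log2(x / t) for x in col if x > 0)
        total += t * 2.0**h
    return total / (2.0 * m) / (P + A)


def ie_oracle(M, denominator="all_cells"):
    P, A = len(M), len(M[0])
    m = sum(sum(row) for row in M)
    h = -sum(
        (x / m) * math.log(x / m) for row in M for x in row if x > 0
    )
    if denominator == "all_cells":
        denom = math.log(P * A)
    else:
        denom = math.log(sum(1 for row in M for x in row if x > 0))
    return h / denom if denom > 0 else 0.0


def wnodf_oracle(M):
    P, A = len(M), len(M[0])

    def pair_scores(lines):
        totals = [sum(line) for line in lines]
        order = sorted(range(len(lines)), key=lambda i: (-totals[i], i))
        scores = []
        for ui in range(len(order)):
            for vi in range(ui + 1, len(order)):
                u, v = order[ui], order[vi]
                if totals[u] > totals[v]:
                    filled = sum(1 for c in range(len(lines[v])) if lines[v][c] > 0)
                    if filled == 0:
                        scores.append(0.0)
                    else:
                        over = sum(
                            1
                            for c in range(len(lines[v]))
                            if 0 < lines[v][c] < lines[u][c]
                        )
                        scores.append(100.0 * over / filled)
                else:
                    scores.append(0.0)
        return scores

    rows = [list(M[i]) for i in range(P)]
    cols = [[M[i][j] for i in range(P)] for j in range(A)]
    scores = pair_scores(rows) + pair_scores(cols)
    return sum(scores) / len(scores)


def h2prime_oracle(M):
    P, A = len(M), len(M[0])
    m = sum(sum(row) for row in M)
    h2 = -sum((x / m) * math.log(x / m) for row in M for x in row if x > 0)
    row_tot = [sum(M[i]) for i in range(P)]
    col_tot = [sum(M[i][j] for i in range(P)) for j in range(A)]
    h2max = 0.0
    for i in range(P):
        for j in range(A):
            p = row_tot[i] * col_tot[j] / (m * m)
            if p > 0:
                h2max -= p * math.log(p)
    r, c = list(row_tot), list(col_tot)
    h2min = 0.0
    while sum(r) > 0:
        i = max(range(P), key=lambda k: (r[k], -k))
        j = max(range(A), key=lambda k: (c[k], -k))
        x = min(r[i], c[j])
        h2min -= (x / m) * math.log(x / m)
        r[i] -= x
        c[j] -= x
    if h2max - h2min <= 1e-12:
        return 0.0
    return min(1.0, max(0.0, (h2max - h2) / (h2max - h2min)))


def d_prime_oracle(M, side):
    P, A = len(M), len(M[0])
    if side == "bee":
        M = [[M[i][j] for i in range(P)] for j in range(A)]
    m = sum(sum(row) for row in M)
    partner_tot = [sum(row[j] for row in M) for j in range(len(M[0]))]
    q = [t / m for t in partner_tot]

    def kl(counts):
        t = sum(counts)
        return sum(
            (x / t) * math.log((x / t) / q[j]) for j, x in enumerate(counts) if x > 0
        )

    out = []
    for row in M:
        t = sum(row)
        order = sorted(range(len(q)), key=lambda j: (q[j], j))
        alloc = [0.0] * len(q)
        remaining = float(t)
        for j in order:
            take = min(remaining, float(partner_tot[j]))
            alloc[j] = take
            remaining -= take
            if remaining <= 0:
                break
        dmax = kl(alloc)
        d = kl(row)
        out.append(0.0 if dmax <= 1e-12 else min(1.0, d / dmax))
    return out


def upgma_oracle(values):
    """Quadratic-recompute UPGMA; returns the list of member partitions and
    merge heights, with the same tie-break as the package (lowest original
    leaf-index pair, cluster represented by its smallest member)."""
    clusters = [[i] for i in range(len(values))]
    heights = []
    steps = [sorted(tuple(c) for c in clusters)]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = sum(
                    abs(values[i] - values[j])
                    for i in clusters[a]
                    for j in clusters[b]
                ) / (len(clusters[a]) * len(clusters[b]))
                ra, rb = min(clusters[a]), min(clusters[b])
                key = (d, min(ra, rb), max(ra, rb))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _, _), a, b = best
        heights.append(d)
        merged = sorted(clusters[a] + clusters[b])
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
        steps.append(sorted(tuple(c) for c in clusters))
    return steps, heights


def betweenness_oracle(adj):
    """All-pairs shortest-path enumeration betweenness (normalized) for a
    small undirected graph given as an adjacency dict node -> set(nodes)."""
    import itertools
    from collections import deque

    nodes = sorted(adj)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        # BFS to count shortest paths through each vertex
        dist = {s: 0}
        npaths = {s: 1}
        order = []
        dq = deque([s])
        while dq:
            u = dq.popleft()
            order.append(u)
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    npaths[w] = 0
                    dq.append(w)
                if dist[w] == dist[u] + 1:
                    npaths[w] += npaths[u]
        if t not in dist:
            continue
        # count, for each v, shortest s-t paths passing through v
        for v in nodes:
            if v in (s, t) or v not in dist:
                continue
            if dist[v] + _bfs_dist(adj, v, t) == dist[t]:
                through = npaths[v] * _npaths(adj, v, t)
                score[v] += through / npaths[t]
    norm = (n - 1) * (n - 2) / 2.0
    return {v: s / norm for v, s in score.items()}


def _bfs_dist(adj, s, t):
    from collections import deque

    dist = {s: 0}
    dq = deque([s])
    while dq:
        u = dq.popleft()
        if u == t:
            return dist[u]
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                dq.append(w)
    return float("inf")


def _npaths(adj, s, t):
    from collections import deque

    dist = {s: 0}
    npaths = {s: 1}
    dq = deque([s])
    while dq:
        u = dq.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                npaths[w] = 0
                dq.append(w)
            if dist[w] == dist[u] + 1:
                npaths[w] += npaths[u]
    return npaths.get(t, 0)
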