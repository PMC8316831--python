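"""Independent brute-force reference implementations for cross-checks.

These deliberately avoid the package's computation path (BFS via
scipy.sparse.csgraph, sparse triangle counting): distances come from a
pure-Python Floyd-Warshall, clustering from direct neighbor-pair
enumeration, and density/centralization from literal formula evaluation.
"""

import math


def floyd_warshall_L(net, mode="reachable"):
    """Mean shortest-path distance over unordered reachable vertex pairs."""
    vs = net.vertices
    index = {v: i for i, v in enumerate(vs)}
    n = len(vs)
    inf = math.inf
    d = [[0 if i == j else inf for j in range(n)] for i in range(n)]
    for (u, v), _ in net.edges():
        i, j = index[u], index[v]
        d[i][j] = d[j][i] = 1
    for k in range(n):
        dk = d[k]
        for i in range(n):
            dik = d[i][k]
            if dik == inf:
                continue
            di = d[i]
            for j in range(n):
                alt = dik + dk[j]
                if alt < di[j]:
                    di[j] = alt
    dists = [d[i][j] for i in range(n) for j in range(i + 1, n)]
    finite = [x for x in dists if x < inf]
    if mode == "reachable":
        return sum(finite) / len(finite)
    if mode == "all-pairs":
        return sum(dists) / len(dists)  # inf if disconnected
    raise ValueError(mode)


def enumeration_clustering(net):
    """Global C by direct enumeration of neighbor pairs, per definition."""
    total = 0.0
    for v in net.vertices:
        nbrs = sorted(net.neighbors(v))
        k = len(nbrs)
        if k < 2:
            continue
        e = sum(
            1
            for a in range(k)
            for b in range(a + 1, k)
            if net.has_edge(nbrs[a], nbrs[b])
        )
        total += 2.0 * e / (k * (k - 1))
    return total / net.N


def direct_density(net):
    n, m = net.N, net.M
    return m / (n * (n - 1) / 2)


def direct_centralization(net):
    n = net.N
    k_max = max(len(net.neighbors(v)) for v in net.vertices)
    rho = direct_density(net)
    return (n / (n - 1)) * (k_max / (n - 1) - rho)


def direct_degrees(net):
    return {v: len(net.neighbors(v)) for v in net.vertices}
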