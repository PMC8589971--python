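"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (dict-based BFS, explicit
path enumeration, O(N^2) pair loops) and deliberately shares no code with
the package internals it checks.
"""
from collections import deque
from itertools import combinations


def bfs_dict(adj, source):
    """Plain BFS over an adjacency dict {u: iterable of neighbors}."""
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def adj_dict(net):
    return {i: [int(v) for v in net.adjacency[i]] for i in range(net.N)}


def all_shortest_paths(adj, s, t):
    """Enumerate every shortest s-t path explicitly (small graphs only)."""
    dist = bfs_dict(adj, s)
    if t not in dist:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for v in adj[u]:
            if dist.get(v) == dist[u] + 1 and dist[v] <= dist[t]:
                extend(path + [v])

    extend([s])
    return [p for p in paths if len(p) - 1 == dist[t]]


def brute_betweenness(net):
    """BC by explicit enumeration of all shortest paths per unordered pair."""
    adj = adj_dict(net)
    bc = [0.0] * net.N
    for s, t in combinations(range(net.N), 2):
        paths = all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for i in range(net.N):
            if i in (s, t):
                continue
            through = sum(1 for p in paths if i in p)
            bc[i] += through / len(paths)
    return bc


def brute_closeness(net):
    """Component-scaled closeness from scratch: (n_i/(N-1)) * (n_i/sum d)."""
    adj = adj_dict(net)
    out = []
    for i in range(net.N):
        dist = bfs_dict(adj, i)
        reach = len(dist) - 1
        if reach == 0:
            out.append(0.0)
            continue
        total = sum(dist.values())
        out.append((reach / (net.N - 1)) * (reach / total))
    return out


def brute_tau(x, y):
    """Eq.-style Kendall tau by pair enumeration, ties counted as neither."""
    n = len(x)
    plus = minus = 0
    for i, j in combinations(range(n), 2):
        dx = int(x[i] > x[j]) - int(x[i] < x[j])
        dy = int(y[i] > y[j]) - int(y[i] < y[j])
        if dx * dy > 0:
            plus += 1
        elif dx * dy < 0:
            minus += 1
    return 2 * (plus - minus) / (n * (n - 1))


def brute_gravity(net, mass, radius):
    """Naive all-pairs gravity score: BFS distances, direct double loop."""
    adj = adj_dict(net)
    out = []
    for i in range(net.N):
        dist = bfs_dict(adj, i)
        s = 0.0
        for j in range(net.N):
            d = dist.get(j)
            if j != i and d is not None and d <= radius:
                s += mass[i] * mass[j] / d**2
        out.append(s)
    return out
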