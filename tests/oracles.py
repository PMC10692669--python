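"""Independent brute-force oracles used by the test suite.

Each oracle reimplements a statistic or construction from scratch, by the
most direct (usually slow) route, and stays independent of the package
code paths it checks.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
from shapely.geometry import box, Polygon


def running_sum_es(scores, members, down, weight=1.0, statistic="area"):
    """Plain-python running-sum enrichment score.

    ``scores``: dict site -> score. ``members``: set of member sites.
    ``down``: set of member sites with down direction. Adjusted score for
    down members is negated; sites are sorted by descending adjusted score
    (stable on the input order for ties); hits increment the running sum
    by |adjusted|^weight normalized by the hit total, misses decrement by
    1/(#misses); ES is the mean of the running sum ("area"), or the most
    extreme deviation ("max").
    """
    sites = list(scores)
    adjusted = {s: (-scores[s] if s in down else scores[s]) for s in sites}
    order = sorted(range(len(sites)), key=lambda i: -adjusted[sites[i]])
    hit_total = sum(abs(adjusted[s]) ** weight for s in members)
    n_miss = len(sites) - len(members)
    running = 0.0
    path = []
    for i in order:
        s = sites[i]
        if s in members:
            running += abs(adjusted[s]) ** weight / hit_total
        else:
            running -= 1.0 / n_miss
        path.append(running)
    if statistic == "area":
        return sum(path) / len(path)
    return max(path, key=abs)


def brute_force_subnetwork(a, node_fdr=0.05, edge_fdr=0.05, max_path_len=2):
    """Exhaustive-path reference for subnetwork extraction.

    Enumerates ALL simple directed paths up to ``max_path_len`` edges
    between perturbed-node pairs, keeps those of minimal length per pair,
    unions them with perturbed edges, and picks the largest undirected
    component by explicit scan (same tie-break: size, total |NES|,
    lexicographically smallest node set).

    Returns (nodes, edges) as sets.
    """
    p_nodes = {
        n for n, d in a.nodes(data=True) if d.get("fdr") is not None and d["fdr"] <= node_fdr
    }
    p_edges = {
        (u, v)
        for u, v, d in a.edges(data=True)
        if d.get("fdr") is not None and d["fdr"] <= edge_fdr
    }
    if not p_nodes and not p_edges:
        return set(), set()

    def all_paths_upto(s, t, k):
        found = []
        stack = [(s, [s])]
        while stack:
            node, path = stack.pop()
            if node == t and len(path) > 1:
                found.append(tuple(path))
                continue
            if len(path) - 1 >= k:
                continue
            for nxt in a.successors(node):
                if nxt not in path:
                    stack.append((nxt, path + [nxt]))
        return found

    cand_nodes = set(p_nodes)
    cand_edges = set(p_edges)
    for u, v in p_edges:
        cand_nodes.update((u, v))
    for s, t in itertools.permutations(sorted(p_nodes), 2):
        paths = all_paths_upto(s, t, max_path_len)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        for p in paths:
            if len(p) == shortest:
                cand_nodes.update(p)
                cand_edges.update(zip(p[:-1], p[1:]))

    # explicit component scan on the undirected view of the candidates
    adjacency = {n: set() for n in cand_nodes}
    for u, v in cand_edges:
        adjacency[u].add(v)
        adjacency[v].add(u)
    seen = set()
    components = []
    for n in cand_nodes:
        if n in seen:
            continue
        comp = set()
        queue = [n]
        while queue:
            x = queue.pop()
            if x in comp:
                continue
            comp.add(x)
            queue.extend(adjacency[x] - comp)
        seen |= comp
        components.append(comp)

    def key(comp):
        nes = sum(abs(a.nodes[n].get("nes", 0.0)) for n in comp)
        inv = tuple(tuple(-ord(c) for c in n) for n in sorted(comp))
        return (len(comp), nes, inv)

    best = max(components, key=key)
    edges = {(u, v) for u, v in cand_edges if u in best and v in best}
    return best, edges


def clipped_voronoi_adjacency(points, frame, min_len=1e-9):
    """Voronoi adjacency via explicit polygon construction and clipping.

    Builds each cell's polygon by half-plane intersection against every
    other site, clips to the frame, and declares neighbors when the shared
    boundary has positive length. O(n^2) per cell but entirely independent
    of any ridge bookkeeping.
    """
    pts = np.asarray(points, float)
    n = len(pts)
    frame_poly = box(0.0, 0.0, *frame)
    cells = []
    for i in range(n):
        poly = frame_poly
        for j in range(n):
            if i == j:
                continue
            mid = (pts[i] + pts[j]) / 2
            d = pts[j] - pts[i]
            norm = math.hypot(*d)
            d = d / norm
            # half-plane {x : (x - mid) . d <= 0} as a big clipped polygon
            t = np.array([-d[1], d[0]])
            big = 10 * max(frame)
            quad = Polygon(
                [
                    mid + t * big,
                    mid - t * big,
                    mid - t * big - d * big,
                    mid + t * big - d * big,
                ]
            )
            poly = poly.intersection(quad)
            if poly.is_empty:
                break
        cells.append(poly)
    # cells are clipped independently, so their boundaries agree only to
    # float precision; measure the shared boundary through a thin buffer
    # band (area / width estimates the shared length)
    tol = 1e-6
    edges = set()
    for i in range(n):
        buffered = cells[i].buffer(tol)
        for j in range(i + 1, n):
            band = buffered.intersection(cells[j])
            if band.area / tol > max(min_len, 1e-3):
                edges.add((i, j))
    return edges


def fisher_two_sided(table):
    """Two-sided Fisher p by full enumeration of tables with fixed margins,
    summing point probabilities <= the observed table's."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def point(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    p_obs = point(a)
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = point(k)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return total


def dense_eigenvector_centrality(adj):
    """Max-normalized principal eigenvector from a dense symmetric
    eigendecomposition."""
    vals, vecs = np.linalg.eigh(adj)
    v = np.abs(vecs[:, np.argmax(vals)])
    return v / v.max()
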