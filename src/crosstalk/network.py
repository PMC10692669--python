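"""Prior-knowledge kinase subnetwork reconstruction.

The prior is a directed, signed causal signaling network (SIGNOR-style):
nodes are signaling entities (gene symbols), edges carry an effect sign,
a mechanism and the phospho-residues on the target through which the
interaction acts. Enrichment results annotate nodes (kinase-signature NES
and FDR) and differential phosphosites annotate edges (log2FC and FDR of
the matching residue).

A perturbation subnetwork is built from *perturbed nodes* (signature
FDR <= 0.05) and *perturbed edges* (phosphosite FDR <= 0.05): all directed
shortest paths of length <= 2 between ordered pairs of perturbed nodes are
combined with the perturbed edges, and the largest (undirected) connected
component is kept. Redundant unannotated shortest paths are pruned when a
fully phosphosite-annotated alternative exists. Treatment subnetworks merge
into per-sample networks on which degree and eigenvector centralities and
mutation overrepresentation (two-sided Fisher) are computed.
"""

from __future__ import annotations

import itertools
import logging
import re
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PRIOR_COLUMNS = ["ENTITYA", "ENTITYB", "EFFECT", "MECHANISM", "RESIDUE"]
_RESIDUE_RE = re.compile(r"^[A-Z]\d+$")


def _parse_effect(value) -> int:
    s = str(value).strip().lower()
    if s in {"1", "+1", "up-regulates", "up-regulates activity"} or s.startswith("up-regulates"):
        return 1
    if s in {"-1", "down-regulates", "down-regulates activity"} or s.startswith("down-regulates"):
        return -1
    raise ValueError(f"unrecognized effect {value!r}")


def load_prior(path) -> nx.DiGraph:
    """Read a SIGNOR-style TSV into a directed signed graph.

    Required columns: ENTITYA, ENTITYB, EFFECT, MECHANISM, RESIDUE (RESIDUE
    may hold a single residue like ``S473`` or a semicolon list). Self-loops
    are dropped (counted in the log); duplicate A->B rows merge into one
    edge whose residue set is the union.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PRIOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"prior network file missing column(s): {', '.join(missing)}")
    g = nx.DiGraph()
    n_self = 0
    for _, row in df.iterrows():
        a, b = row["ENTITYA"], row["ENTITYB"]
        if a == b:
            n_self += 1
            continue
        residues = frozenset(
            r for r in str(row["RESIDUE"] or "").split(";") if r and r.lower() != "nan"
        )
        for r in residues:
            if not _RESIDUE_RE.match(r):
                raise ValueError(f"malformed residue {r!r} on edge {a}->{b}")
        sign = _parse_effect(row["EFFECT"])
        if g.has_edge(a, b):
            g[a][b]["residues"] = g[a][b]["residues"] | residues
        else:
            g.add_edge(a, b, sign=sign, mechanism=row["MECHANISM"], residues=residues)
    if n_self:
        logger.info("dropped %d self-loop(s) from prior network", n_self)
    if g.number_of_edges() == 0:
        raise ValueError("prior network has no edges")
    return g


def annotate(
    prior: nx.DiGraph,
    enrichment: pd.DataFrame | None = None,
    diff: pd.DataFrame | None = None,
) -> nx.DiGraph:
    """Attach activity and phosphosite statistics to a copy of the prior.

    Node attributes ``nes``/``fdr`` come from enrichment rows whose
    signature name equals the node symbol. Edge attributes ``log2fc``/
    ``fdr``/``site`` come from the differential site (on the edge's target
    protein, at one of the edge's annotated residues) with the smallest
    FDR. Unannotated elements carry no attribute at all — absence encodes
    "not measured", never zero.
    """
    g = prior.copy()
    if enrichment is not None and not enrichment.empty:
        by_sig = enrichment.set_index("signature")
        for node in g.nodes:
            if node in by_sig.index:
                row = by_sig.loc[node]
                g.nodes[node]["nes"] = float(row["nes"])
                g.nodes[node]["fdr"] = float(row["fdr"])
    if diff is not None and not diff.empty:
        sites = {
            (p, f"{r}{int(q)}"): (lfc, fdr)
            for p, r, q, lfc, fdr in zip(
                diff["protein"], diff["residue"], diff["position"], diff["log2fc"], diff["fdr"]
            )
        }
        for u, v, data in g.edges(data=True):
            best = None
            for res in data.get("residues", ()):  # residues live on the target
                hit = sites.get((v, res))
                if hit is not None and (best is None or hit[1] < best[1][1]):
                    best = (res, hit)
            if best is not None:
                res, (lfc, fdr) = best
                data["log2fc"] = float(lfc)
                data["fdr"] = float(fdr)
                data["site"] = f"{v};{res}"
    return g


@dataclass
class Subnetwork:
    """An extracted perturbation subnetwork.

    ``graph`` is a directed subgraph of the annotated prior.
    ``node_provenance``/``edge_provenance`` record why each element is
    present (subsets of {"perturbed_node", "perturbed_edge",
    "path_connector"}); ``paths`` keeps, per ordered perturbed-node pair,
    the retained shortest paths (tuples of nodes) for downstream pruning.
    """

    graph: nx.DiGraph
    node_provenance: dict = field(default_factory=dict)
    edge_provenance: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)
    treatment: str | None = None
    parent: nx.DiGraph | None = None

    @property
    def empty(self) -> bool:
        return self.graph.number_of_nodes() == 0

    def nodes(self):
        return set(self.graph.nodes)

    def edges(self):
        return set(self.graph.edges)


def _component_key(g: nx.DiGraph, comp: set) -> tuple:
    """Sort key for the largest-component tie-break: size, then total |NES|,
    then lexicographically smallest node set (preferred = max under key)."""
    total_nes = sum(abs(g.nodes[n].get("nes", 0.0)) for n in comp)
    # invert lexicographic order so that max() prefers the smallest node set
    inv = tuple(tuple(-ord(c) for c in n) for n in sorted(comp))
    return (len(comp), total_nes, inv)


def extract_subnetwork(
    a: nx.DiGraph,
    node_fdr: float = 0.05,
    edge_fdr: float = 0.05,
    max_path_len: int = 2,
    directed: bool = True,
    treatment: str | None = None,
) -> Subnetwork:
    """Extract the perturbation subnetwork from an annotated prior.

    Perturbed nodes are those with node FDR <= ``node_fdr``; perturbed
    edges those with edge FDR <= ``edge_fdr`` (thresholds inclusive). For
    every ordered pair of distinct perturbed nodes whose directed
    shortest-path distance is <= ``max_path_len`` (hop count), ALL shortest
    paths are collected. Path edges and perturbed edges (with endpoints)
    form the candidate graph; the largest connected component under
    undirected connectivity is returned, ties broken by total |NES| then by
    lexicographically smallest node set. ``directed=False`` computes paths
    on the undirected projection instead (the prior is causal, so the
    directed reading is the default).
    """
    p_nodes = {n for n, d in a.nodes(data=True) if d.get("fdr") is not None and d["fdr"] <= node_fdr}
    p_edges = {(u, v) for u, v, d in a.edges(data=True) if d.get("fdr") is not None and d["fdr"] <= edge_fdr}
    if not p_nodes and not p_edges:
        warnings.warn("no perturbed nodes or edges; returning empty subnetwork")
        return Subnetwork(nx.DiGraph(), treatment=treatment, parent=a)

    search = a if directed else a.to_undirected(as_view=True)

    cand = nx.DiGraph()
    node_prov: dict = {n: {"perturbed_node"} for n in p_nodes}
    edge_prov: dict = {}
    paths: dict = {}
    for n in p_nodes:
        cand.add_node(n)
    for u, v in p_edges:
        cand.add_edge(u, v)
        edge_prov.setdefault((u, v), set()).add("perturbed_edge")
        for n in (u, v):
            node_prov.setdefault(n, set()).add("perturbed_edge")

    for s, t in itertools.permutations(sorted(p_nodes), 2):
        try:
            dist = nx.shortest_path_length(search, s, t)
        except nx.NetworkXNoPath:
            continue
        if dist > max_path_len:
            continue
        pair_paths = []
        for path in nx.all_shortest_paths(search, s, t):
            pair_paths.append(tuple(path))
            for x, y in zip(path[:-1], path[1:]):
                u, v = (x, y) if a.has_edge(x, y) else (y, x)
                cand.add_edge(u, v)
                edge_prov.setdefault((u, v), set()).add("path_connector")
            for n in path[1:-1]:
                node_prov.setdefault(n, set()).add("path_connector")
        if pair_paths:
            paths[(s, t)] = pair_paths

    components = list(nx.connected_components(cand.to_undirected(as_view=True)))
    best = max(components, key=lambda c: _component_key(a, c))
    sub = nx.DiGraph()
    sub.add_nodes_from((n, dict(a.nodes[n])) for n in best)
    sub.add_edges_from(
        (u, v, dict(a[u][v]) if a.has_edge(u, v) else {})
        for u, v in cand.edges
        if u in best and v in best
    )
    return Subnetwork(
        graph=sub,
        node_provenance={n: p for n, p in node_prov.items() if n in best},
        edge_provenance={e: p for e, p in edge_prov.items() if e[0] in best and e[1] in best},
        paths={k: v for k, v in paths.items() if k[0] in best},
        treatment=treatment,
        parent=a,
    )


def _path_edges(path: tuple, g: nx.DiGraph) -> list[tuple]:
    out = []
    for x, y in zip(path[:-1], path[1:]):
        out.append((x, y) if g.has_edge(x, y) else (y, x))
    return out


def prune_redundant_paths(s: Subnetwork) -> Subnetwork:
    """Drop unannotated alternative shortest paths.

    For each perturbed-node pair connected by several shortest paths, paths
    whose every edge carries a measured phosphosite (a ``log2fc``
    annotation) are preferred. If at least one fully annotated path exists,
    unannotated alternatives are removed — but only elements that serve no
    other retained path and are not themselves perturbed. Pruning that
    would disconnect the subnetwork is rolled back for that pair.
    """
    if s.empty or not s.paths:
        return s
    g = s.graph.copy()
    node_prov = {n: set(p) for n, p in s.node_provenance.items()}
    edge_prov = {e: set(p) for e, p in s.edge_provenance.items()}
    retained = {pair: list(paths) for pair, paths in s.paths.items()}

    for pair in sorted(retained):
        paths = retained[pair]
        if len(paths) < 2:
            continue
        annotated = [
            p for p in paths
            if all("log2fc" in g[u][v] for u, v in _path_edges(p, g))
        ]
        if not annotated or len(annotated) == len(paths):
            continue
        keep_paths = annotated
        drop_paths = [p for p in paths if p not in annotated]

        # elements used by any retained path (over all pairs, with this
        # pair's unannotated alternatives removed)
        trial = {k: (keep_paths if k == pair else v) for k, v in retained.items()}
        used_edges = set()
        used_nodes = set()
        for plist in trial.values():
            for p in plist:
                used_edges.update(_path_edges(p, g))
                used_nodes.update(p)

        drop_edges = set()
        drop_nodes = set()
        for p in drop_paths:
            for e in _path_edges(p, g):
                if e not in used_edges and "perturbed_edge" not in edge_prov.get(e, set()):
                    drop_edges.add(e)
            for n in p[1:-1]:
                if n not in used_nodes and "perturbed_node" not in node_prov.get(n, set()):
                    drop_nodes.add(n)
        drop_nodes = {
            n for n in drop_nodes
            if all((e[0] != n and e[1] != n) or e in drop_edges for e in g.edges)
        }
        if not drop_edges and not drop_nodes:
            continue
        trial_g = g.copy()
        trial_g.remove_edges_from(drop_edges)
        trial_g.remove_nodes_from(drop_nodes)
        if trial_g.number_of_nodes() and nx.is_connected(trial_g.to_undirected(as_view=True)):
            g = trial_g
            retained[pair] = keep_paths
            for e in drop_edges:
                edge_prov.pop(e, None)
            for n in drop_nodes:
                node_prov.pop(n, None)
        # else: rollback for this pair (keep g unchanged)

    return Subnetwork(
        graph=g,
        node_provenance=node_prov,
        edge_provenance=edge_prov,
        paths=retained,
        treatment=s.treatment,
        parent=s.parent,
    )


def merge_subnetworks(subs: list[Subnetwork]) -> Subnetwork:
    """Union of treatment subnetworks into a per-sample network.

    Per-node ``n_subgraphs`` counts how many input subnetworks contain the
    node. Treatment-specific node/edge attributes are kept side by side
    under ``<attr>__<treatment>`` keys, never averaged. All inputs must
    share the same parent annotated network.
    """
    if not subs:
        raise ValueError("nothing to merge")
    ref = subs[0].parent
    for s in subs[1:]:
        if s.parent is ref:
            continue
        if (
            s.parent is None
            or ref is None
            or set(s.parent.nodes) != set(ref.nodes)
            or set(s.parent.edges) != set(ref.edges)
        ):
            raise ValueError("subnetworks come from different parent networks")
    g = nx.DiGraph()
    counts: dict = {}
    node_prov: dict = {}
    edge_prov: dict = {}
    for k, s in enumerate(subs):
        label = s.treatment or f"t{k}"
        for n, data in s.graph.nodes(data=True):
            g.add_node(n)
            counts[n] = counts.get(n, 0) + 1
            for key, val in data.items():
                g.nodes[n][f"{key}__{label}"] = val
            node_prov.setdefault(n, set()).update(s.node_provenance.get(n, set()))
        for u, v, data in s.graph.edges(data=True):
            g.add_edge(u, v)
            for key, val in data.items():
                g[u][v][f"{key}__{label}"] = val
            edge_prov.setdefault((u, v), set()).update(s.edge_provenance.get((u, v), set()))
    nx.set_node_attributes(g, counts, "n_subgraphs")
    return Subnetwork(
        graph=g,
        node_provenance=node_prov,
        edge_provenance=edge_prov,
        treatment=None,
        parent=subs[0].parent,
    )


def _eigenvector_power(adj: np.ndarray, tol: float = 1e-10, max_iter: int = 100000) -> np.ndarray:
    """Principal eigenvector of a symmetric adjacency by power iteration.

    A unit shift (A + I) guarantees convergence on bipartite graphs; the
    result is max-normalized. On a disconnected graph the vector
    concentrates on the spectrally dominant component (documented
    behavior).
    """
    n = adj.shape[0]
    x = np.ones(n)
    shifted = adj + np.eye(n)
    for _ in range(max_iter):
        y = shifted @ x
        norm = np.max(np.abs(y))
        if norm == 0:
            return np.ones(n)
        y /= norm
        if np.max(np.abs(y - x)) < tol:
            x = y
            break
        x = y
    x = np.abs(x)
    return x / x.max()


def centralities(s: Subnetwork) -> pd.DataFrame:
    """Degree and eigenvector centralities on the undirected projection.

    Degree centrality is degree/(n-1); eigenvector centrality is computed
    by power iteration (tolerance 1e-10) and max-normalized to 1. A single
    isolated node gets degree 0 and eigenvector 1 by convention. The
    ``n_subgraphs`` node attribute (from :func:`merge_subnetworks`) is
    carried through when present.
    """
    if s.empty:
        raise ValueError("empty subnetwork")
    u = nx.Graph(s.graph.to_undirected(as_view=True))
    nodes = sorted(u.nodes)
    n = len(nodes)
    adj = nx.to_numpy_array(u, nodelist=nodes)
    deg = adj.sum(axis=1) / (n - 1) if n > 1 else np.zeros(n)
    eig = _eigenvector_power(adj) if n > 1 else np.ones(n)
    return pd.DataFrame(
        {
            "node": nodes,
            "degree_centrality": deg,
            "eigenvector_centrality": eig,
            "n_subgraphs": [s.graph.nodes[v].get("n_subgraphs", 1) for v in nodes],
        }
    )


@dataclass
class FisherResult:
    """2x2 mutation-overrepresentation table and its two-sided Fisher test."""

    table: np.ndarray
    odds_ratio: float
    pvalue: float


def mutation_enrichment(s: Subnetwork, prior: nx.DiGraph, mutated_genes: set) -> FisherResult:
    """Two-sided Fisher's exact test of coding-mutation overrepresentation.

    The table compares mutated/non-mutated counts inside the subnetwork
    against the background (prior nodes not in the subnetwork). The
    two-sided p sums hypergeometric point probabilities <= the observed
    table's (the convention of mainstream statistics libraries).
    """
    sub_nodes = s.nodes()
    background = set(prior.nodes) - sub_nodes
    if not background:
        raise ValueError("subnetwork covers the whole prior; background is empty")
    mutated = set(mutated_genes)
    table = np.array(
        [
            [len(sub_nodes & mutated), len(sub_nodes - mutated)],
            [len(background & mutated), len(background - mutated)],
        ]
    )
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return FisherResult(table=table, odds_ratio=float(odds), pvalue=float(p))
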