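"""Spatial single-cell statistics for imaging-mass-cytometry cell maps.

Input is a post-segmentation cell table for one region of interest (ROI):
cell centroids in micrometers, a phenotype label per cell, and per-marker
positive-area fractions. Direct spatial contact is defined through the
Voronoi tessellation: two cells are neighbors when their Voronoi polygons,
clipped to the ROI frame, share a boundary segment of positive length.

Attraction and avoidance between phenotype pairs are scored against a
label-permutation null: cell positions (and hence the neighbor graph) stay
fixed while phenotype labels are shuffled, preserving the number of cells
of each type. A Z score and permutation p value per pair support calls at
|Z| > 2 and p < 0.01; per-ROI Z scores combine across a cohort with
Stouffer's method (sum Z / sqrt(k)). PD-1+/PD-L1+ microaggregates are
connected components of the neighbor graph restricted to flagged cells
containing at least one PD-L1+ tumor cell and one PD-1+ immune cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import Voronoi

logger = logging.getLogger(__name__)

#: jitter applied to exactly duplicated coordinates, in micrometers
_DUPLICATE_JITTER_UM = 1e-6
#: minimum shared-facet length counted as contact, in micrometers
_MIN_FACET_LEN_UM = 1e-9

CELL_COLUMNS = ["cell_id", "roi_id", "x_um", "y_um", "phenotype"]


@dataclass
class CellMap:
    """Segmented cells of one ROI.

    ``cells`` holds ``cell_id, roi_id, x_um, y_um, phenotype`` plus one
    column per marker with the positive-area fraction in [0, 1];
    ``frame_um`` is the ROI width/height in micrometers (origin at 0,0).
    """

    cells: pd.DataFrame
    frame_um: tuple[float, float] = (1000.0, 1000.0)

    def __post_init__(self) -> None:
        missing = [c for c in CELL_COLUMNS if c not in self.cells.columns]
        if missing:
            raise ValueError(f"cell table missing column(s): {', '.join(missing)}")
        w, h = self.frame_um
        x = self.cells["x_um"].to_numpy(float)
        y = self.cells["y_um"].to_numpy(float)
        if len(x) and (x.min() < 0 or y.min() < 0 or x.max() > w or y.max() > h):
            raise ValueError("cell coordinates fall outside the ROI frame")

    def __len__(self) -> int:
        return len(self.cells)

    def markers(self) -> list[str]:
        return [c for c in self.cells.columns if c not in CELL_COLUMNS]


def marker_positive(c: CellMap, marker: str, threshold: float = 0.10) -> pd.Series:
    """Per-cell marker positivity: positive-area fraction >= threshold.

    The default 10% threshold means a cell counts as positive when the
    marker is detected in at least a tenth of its area (inclusive bound).
    """
    if marker not in c.cells.columns:
        raise KeyError(f"unknown marker {marker!r}")
    s = c.cells[marker] >= threshold
    s.index = c.cells["cell_id"]
    return s


def densities(c: CellMap) -> pd.Series:
    """Cells per square millimeter, by phenotype (1 mm^2 = 1e6 um^2)."""
    w, h = c.frame_um
    area_mm2 = w * h / 1e6
    if area_mm2 <= 0:
        raise ValueError("ROI frame area must be positive")
    return c.cells.groupby("phenotype").size() / area_mm2


def _reflect(points: np.ndarray, frame: tuple[float, float]) -> np.ndarray:
    """Mirror points across the four frame edges.

    With the mirrored sites present, every original cell's Voronoi region
    is bounded and coincides exactly with the frame-clipped region, so no
    polygon clipping is needed for adjacency. Mirrors that would duplicate
    an original site (points exactly on the boundary) are skipped.
    """
    w, h = frame
    x, y = points[:, 0], points[:, 1]
    mirrors = [
        np.column_stack([-x, y]),
        np.column_stack([2 * w - x, y]),
        np.column_stack([x, -y]),
        np.column_stack([x, 2 * h - y]),
    ]
    out = [points]
    for m in mirrors:
        keep = ~np.any(np.all(np.isclose(m[:, None, :], points[None, :, :]), axis=2), axis=1)
        out.append(m[keep])
    return np.vstack(out)


def voronoi_neighbors(c: CellMap, jitter_seed: int = 0) -> nx.Graph:
    """Voronoi neighbor graph of a cell map.

    Cells are neighbors iff their frame-clipped Voronoi polygons share a
    boundary segment of positive length (point contacts on degenerate
    lattices are excluded). Implemented by mirroring the sites across the
    four ROI edges, so border cells are exactly clipped to the frame, and
    reading adjacency off the surviving finite ridges. Exactly duplicated
    coordinates are jittered by 1e-6 um with the logged ``jitter_seed``.
    """
    n = len(c)
    if n < 3:
        raise ValueError("Voronoi tessellation needs >= 3 cells")
    pts = c.cells[["x_um", "y_um"]].to_numpy(float).copy()
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError(
            "cells are collinear; Voronoi adjacency undefined — add cells or jitter"
        )
    # jitter exact duplicates so every site is distinct
    _, inverse, counts = np.unique(pts, axis=0, return_inverse=True, return_counts=True)
    dup = counts[inverse] > 1
    if dup.any():
        rng = np.random.default_rng(jitter_seed)
        logger.info(
            "jittering %d duplicated coordinate(s) by %g um (seed=%d)",
            int(dup.sum()), _DUPLICATE_JITTER_UM, jitter_seed,
        )
        pts[dup] += rng.normal(0, _DUPLICATE_JITTER_UM, size=(int(dup.sum()), 2))

    aug = _reflect(pts, c.frame_um)
    vor = Voronoi(aug)
    ids = c.cells["cell_id"].to_numpy()
    g = nx.Graph()
    g.add_nodes_from(ids)
    for (i, j), ridge in zip(vor.ridge_points, vor.ridge_vertices):
        if i >= n or j >= n or i == j:
            continue
        if -1 in ridge:
            continue  # unbounded ridges belong to mirror cells only
        v0, v1 = vor.vertices[ridge[0]], vor.vertices[ridge[1]]
        if np.hypot(*(v1 - v0)) > _MIN_FACET_LEN_UM:
            g.add_edge(ids[i], ids[j])
    assert all(not g.has_edge(u, u) for u in g.nodes)
    return g


def voronoi_polygons(c: CellMap, jitter_seed: int = 0) -> list[dict]:
    """Frame-clipped Voronoi polygons as GeoJSON-style records.

    One record per cell: ``{"cell_id", "phenotype", "polygon": [[x, y],
    ...]}``; intended for plotting parity with neighborhood-map figures.
    """
    from shapely.geometry import box, Polygon

    n = len(c)
    if n < 3:
        raise ValueError("Voronoi tessellation needs >= 3 cells")
    pts = c.cells[["x_um", "y_um"]].to_numpy(float)
    aug = _reflect(pts, c.frame_um)
    vor = Voronoi(aug)
    frame = box(0, 0, *c.frame_um)
    out = []
    for k in range(n):
        region = vor.regions[vor.point_region[k]]
        if -1 in region or not region:
            poly = frame  # should not happen with mirrored sites
        else:
            poly = Polygon(vor.vertices[region]).intersection(frame)
        out.append(
            {
                "cell_id": c.cells["cell_id"].iloc[k],
                "phenotype": c.cells["phenotype"].iloc[k],
                "polygon": [list(p) for p in np.asarray(poly.exterior.coords)],
            }
        )
    return out


def _pair_counts(edge_a: np.ndarray, edge_b: np.ndarray, codes: np.ndarray, k: int) -> np.ndarray:
    """Unordered phenotype-pair edge counts for one labeling.

    Returns a (k, k) upper-triangular count matrix over phenotype codes.
    """
    la, lb = codes[edge_a], codes[edge_b]
    lo, hi = np.minimum(la, lb), np.maximum(la, lb)
    flat = np.bincount(lo * k + hi, minlength=k * k)
    return flat.reshape(k, k)


def interaction_test(
    g: nx.Graph,
    labels: pd.Series,
    n_iter: int = 1000,
    seed: int | None = None,
    z_thresh: float = 2.0,
    p_thresh: float = 0.01,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Permutation test for phenotype attraction/avoidance.

    For every unordered phenotype pair (same-type pairs included) the
    observed neighbor-edge count is compared with a null of ``n_iter``
    label permutations over the fixed positions (phenotype counts
    preserved each iteration). Z = (obs - mean_null)/sd_null. The p value
    uses an add-one correction so it is never exactly 0; the default
    ``"two-sided"`` doubles the tail in the direction of the deviation
    (capped at 1), which is calibrated at its nominal level under complete
    spatial randomness. ``alternative="directional"`` reports the raw
    one-sided tail in the direction of Z instead. Calls: ``attraction`` if
    Z > z_thresh and p < p_thresh, ``avoidance`` if Z < -z_thresh and
    p < p_thresh, else ``ns``; pairs with a degenerate null (sd = 0) are
    flagged and not called.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    if alternative not in {"two-sided", "directional"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    labels = labels.reindex([n for n in g.nodes])
    if labels.isna().any():
        raise ValueError("labels missing for some cells in the graph")
    cats = sorted(labels.unique())
    k = len(cats)
    code_of = {c: i for i, c in enumerate(cats)}
    codes = labels.map(code_of).to_numpy()
    node_ix = {n: i for i, n in enumerate(g.nodes)}
    if g.number_of_edges():
        edges = np.array([(node_ix[u], node_ix[v]) for u, v in g.edges])
        ea, eb = edges[:, 0], edges[:, 1]
    else:
        ea = eb = np.array([], dtype=int)

    obs = _pair_counts(ea, eb, codes, k)

    rng = np.random.default_rng(seed)
    null = np.empty((n_iter, k, k), dtype=np.int64)
    perm = codes.copy()
    for it in range(n_iter):
        rng.shuffle(perm)
        null[it] = _pair_counts(ea, eb, perm, k)

    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=0)
    rows = []
    for i in range(k):
        for j in range(i, k):
            o = obs[i, j]
            mu, s = mean[i, j], sd[i, j]
            nn = null[:, i, j]
            p_ge = (1 + int((nn >= o).sum())) / (n_iter + 1)
            p_le = (1 + int((nn <= o).sum())) / (n_iter + 1)
            if s == 0:
                rows.append(
                    dict(phenotype_a=cats[i], phenotype_b=cats[j], observed=int(o),
                         null_mean=mu, null_sd=s, z=np.nan, pvalue=np.nan,
                         call="degenerate")
                )
                continue
            z = (o - mu) / s
            p_dir = p_ge if o >= mu else p_le
            p = min(1.0, 2 * min(p_ge, p_le)) if alternative == "two-sided" else p_dir
            if z > z_thresh and p < p_thresh:
                call = "attraction"
            elif z < -z_thresh and p < p_thresh:
                call = "avoidance"
            else:
                call = "ns"
            rows.append(
                dict(phenotype_a=cats[i], phenotype_b=cats[j], observed=int(o),
                     null_mean=mu, null_sd=s, z=z, pvalue=p, call=call)
            )
    out = pd.DataFrame(rows)
    out.attrs.update(n_iter=n_iter, z_thresh=z_thresh, p_thresh=p_thresh,
                     alternative=alternative)
    return out


def stouffer_combine(z_per_roi) -> float:
    """Cohort Z from per-ROI Z scores: sum(Z_i) / sqrt(k).

    Degenerate ROIs should be excluded upstream; an empty list yields NaN.
    """
    zs = np.asarray([z for z in z_per_roi], dtype=float)
    if zs.size == 0:
        return float("nan")
    return float(zs.sum() / np.sqrt(zs.size))


@dataclass
class Microaggregate:
    """Voronoi-connected component with both PD-L1+ tumor and PD-1+ immune
    cells present."""

    cells: frozenset
    n_pdl1_tumor: int
    n_pd1_immune: int


def _components(edge_a, edge_b, active: np.ndarray) -> list[np.ndarray]:
    """Connected components of the subgraph induced on ``active`` nodes
    (union-find; isolated active nodes form singleton components)."""
    n = len(active)
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for u, v in zip(edge_a, edge_b):
        if active[u] and active[v]:
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[ru] = rv
    groups: dict[int, list[int]] = {}
    for i in np.flatnonzero(active):
        groups.setdefault(find(i), []).append(i)
    return [np.array(v) for v in groups.values()]


def microaggregates(
    g: nx.Graph, tumor_pdl1: pd.Series, immune_pd1: pd.Series
) -> list[Microaggregate]:
    """PD-1+/PD-L1+ microaggregates.

    The neighbor graph is restricted to cells flagged PD-L1+ tumor or
    PD-1+ immune; connected components of the restriction qualify when
    they contain at least one cell of each class.
    """
    nodes = list(g.nodes)
    ix = {nid: i for i, nid in enumerate(nodes)}
    t = tumor_pdl1.reindex(nodes).fillna(False).to_numpy(bool)
    m = immune_pd1.reindex(nodes).fillna(False).to_numpy(bool)
    if g.number_of_edges():
        edges = np.array([(ix[u], ix[v]) for u, v in g.edges])
        ea, eb = edges[:, 0], edges[:, 1]
    else:
        ea = eb = np.array([], dtype=int)
    out = []
    for comp in _components(ea, eb, t | m):
        nt, nm = int(t[comp].sum()), int(m[comp].sum())
        if nt >= 1 and nm >= 1:
            out.append(
                Microaggregate(
                    cells=frozenset(nodes[i] for i in comp),
                    n_pdl1_tumor=nt,
                    n_pd1_immune=nm,
                )
            )
    return out


def microaggregate_test(
    g: nx.Graph,
    tumor_pdl1: pd.Series,
    immune_pd1: pd.Series,
    n_iter: int = 1000,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Permutation test for the number of qualifying microaggregates.

    The two flag sets are permuted independently over the fixed positions
    (class sizes preserved); Z and the add-one permutation p are formed as
    in :func:`interaction_test`. Returns ``(z, p)``; a degenerate null
    (sd = 0, e.g. no flagged cells) returns ``(nan, nan)``.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    nodes = list(g.nodes)
    ix = {nid: i for i, nid in enumerate(nodes)}
    t = tumor_pdl1.reindex(nodes).fillna(False).to_numpy(bool)
    m = immune_pd1.reindex(nodes).fillna(False).to_numpy(bool)
    if g.number_of_edges():
        edges = np.array([(ix[u], ix[v]) for u, v in g.edges])
        ea, eb = edges[:, 0], edges[:, 1]
    else:
        ea = eb = np.array([], dtype=int)

    def stat(tf: np.ndarray, mf: np.ndarray) -> int:
        count = 0
        for comp in _components(ea, eb, tf | mf):
            if tf[comp].any() and mf[comp].any():
                count += 1
        return count

    obs = stat(t, m)
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter, dtype=np.int64)
    tp, mp = t.copy(), m.copy()
    for it in range(n_iter):
        rng.shuffle(tp)
        rng.shuffle(mp)
        null[it] = stat(tp, mp)
    sd = null.std(ddof=0)
    if sd == 0:
        return (float("nan"), float("nan"))
    z = (obs - null.mean()) / sd
    p_ge = (1 + int((null >= obs).sum())) / (n_iter + 1)
    p_le = (1 + int((null <= obs).sum())) / (n_iter + 1)
    if alternative == "two-sided":
        p = min(1.0, 2 * min(p_ge, p_le))
    else:
        p = p_ge if obs >= null.mean() else p_le
    return (float(z), float(p))
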