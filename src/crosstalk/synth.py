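"""Seeded synthetic-data generators for every pipeline input.

Each generator emulates the statistical structure of one study input with a
known planted ground truth, so every downstream stage is testable without
the deposited datasets:

- a directed, signed prior signaling network with per-edge residue
  annotations (SIGNOR-style) and a proteome consistent with them;
- replicated log-normal fragment intensity tables with kinase-downstream
  effects planted for simulated inhibitor treatments;
- a kinase signature database derived from the planted network
  (PTMsigDB-style, one signature per kinase over its outgoing-edge sites);
- spatial cell maps with clustered (parent-daughter) placement for planted
  attraction pairs;
- per-sample coding-mutation gene lists and equicorrelated protein-complex
  abundance matrices.

All randomness flows through explicit ``numpy.random.Generator`` state
derived from an integer seed; identical arguments and seed produce
byte-identical tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from crosstalk.enrichment import SignatureDB, site_id
from crosstalk.phospho import FragmentTable

_AMINO_ACIDS = list("ACDEFGHIKLMNPQRVWY")  # S/T handled via planted sites
_PHOSPHO_LETTERS = ["S", "T", "Y"]
_PHOSPHO_WEIGHTS = [0.6, 0.3, 0.1]

#: log2-scale fragment baseline for background peptides; the absolute
#: intensity prefilter (2000 ~ 2^11) removes a real tail of this
#: distribution, which keeps the filter testable.
BACKGROUND_LOG2_MEAN = 12.0
BACKGROUND_LOG2_SD = 1.0
#: planted peptides sit higher so an inhibition shift of -3 log2 units
#: leaves most treated fragments above the absolute filter
PLANTED_LOG2_MEAN = 14.5
PLANTED_LOG2_SD = 0.3

#: daughter-point scatter of the clustered placement, micrometers
THOMAS_SIGMA_UM = 12.0


@dataclass
class GroundTruth:
    """Planted truth accompanying a generated dataset."""

    rng_seed: int
    planted_target_kinases: dict = field(default_factory=dict)  # treatment -> kinase
    planted_differential_sites: dict = field(default_factory=dict)  # treatment -> set[(prot, res, pos)]
    planted_attractions: set = field(default_factory=set)
    planted_avoidances: set = field(default_factory=set)
    planted_stable_complexes: set = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "rng_seed": self.rng_seed,
            "planted_target_kinases": dict(self.planted_target_kinases),
            "planted_differential_sites": {
                k: sorted([list(s) for s in v]) for k, v in self.planted_differential_sites.items()
            },
            "planted_attractions": sorted([list(p) for p in self.planted_attractions]),
            "planted_avoidances": sorted([list(p) for p in self.planted_avoidances]),
            "planted_stable_complexes": sorted(self.planted_stable_complexes),
        }


def gen_prior_network(
    n_kinases: int,
    n_substrates: int = 0,
    edge_density: float = 0.1,
    seed: int = 0,
) -> nx.DiGraph:
    """Random weakly connected, signed, residue-annotated prior network.

    Kinases (``KIN00``...) may phosphorylate kinases or substrates
    (``SUB00``...); substrates are never sources. ``edge_density`` is the
    fraction of possible kinase->target edges realized; the generator first
    wires a random spanning structure (guaranteeing weak connectivity) and
    then adds random edges up to the requested count. Every edge carries an
    effect sign (+1 with probability 0.7), a mechanism string and 1-2
    residue annotations (e.g. ``S473``) whose positions are unique per
    target protein.
    """
    if n_kinases < 2:
        raise ValueError("need at least 2 kinases")
    if not 0 < edge_density <= 1:
        raise ValueError("edge_density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    kinases = [f"KIN{i:02d}" for i in range(n_kinases)]
    substrates = [f"SUB{i:02d}" for i in range(n_substrates)]
    nodes = kinases + substrates
    possible = n_kinases * (n_kinases - 1) + n_kinases * n_substrates
    n_edges = int(round(edge_density * possible))
    if n_edges < len(nodes) - 1:
        min_density = (len(nodes) - 1) / possible
        raise ValueError(
            f"edge_density {edge_density} cannot connect {len(nodes)} nodes; "
            f"minimum is {min_density:.4f}"
        )

    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    used_positions: dict[str, set[int]] = {n: set() for n in nodes}

    def annotate_edge(u: str, v: str) -> None:
        n_res = 2 if rng.random() < 0.2 else 1
        residues = set()
        for _ in range(n_res):
            for _try in range(50):
                pos = int(rng.integers(5, 150))
                if pos not in used_positions[v]:
                    used_positions[v].add(pos)
                    letter = rng.choice(_PHOSPHO_LETTERS, p=_PHOSPHO_WEIGHTS)
                    residues.add(f"{letter}{pos}")
                    break
        sign = 1 if rng.random() < 0.7 else -1
        g.add_edge(
            u, v,
            sign=sign,
            mechanism="phosphorylation" if sign == 1 else "dephosphorylation",
            residues=frozenset(residues),
        )

    # spanning structure: each node beyond the first gets an incoming edge
    # from a random earlier kinase (kinases listed first)
    for i, v in enumerate(nodes[1:], start=1):
        u = kinases[int(rng.integers(0, min(i, n_kinases)))]
        annotate_edge(u, v)
    remaining = [
        (u, v) for u in kinases for v in nodes if u != v and not g.has_edge(u, v)
    ]
    extra = n_edges - g.number_of_edges()
    if extra > 0 and remaining:
        pick = rng.choice(len(remaining), size=min(extra, len(remaining)), replace=False)
        for ix in sorted(pick):
            annotate_edge(*remaining[ix])
    assert nx.is_weakly_connected(g)
    return g


def gen_proteome(net: nx.DiGraph, seed: int = 0, pad: int = 10) -> dict[str, str]:
    """Random protein sequences consistent with the network's residue
    annotations (the annotated letter is planted at the annotated
    position)."""
    rng = np.random.default_rng(seed)
    proteome = {}
    for node in sorted(net.nodes):
        sites = []
        for _, _, data in net.in_edges(node, data=True):
            for res in data["residues"]:
                sites.append((int(res[1:]), res[0]))
        length = max([p for p, _ in sites], default=20) + pad
        seq = rng.choice(_AMINO_ACIDS, size=length)
        for pos, letter in sites:
            seq[pos - 1] = letter
        proteome[node] = "".join(seq)
    return proteome


def gen_signature_db(net: nx.DiGraph, category: str = "KINASE") -> SignatureDB:
    """One signature per kinase: its outgoing-edge sites with direction
    flags (``u`` for activating edges, ``d`` for inhibitory ones).

    Deterministic given the network; a kinase with no outgoing edges gets
    no signature.
    """
    signatures: dict[str, list[tuple[str, str]]] = {}
    categories: dict[str, str] = {}
    for kinase in sorted(net.nodes):
        members = []
        for _, target, data in sorted(net.out_edges(kinase, data=True)):
            for res in sorted(data["residues"]):
                members.append(
                    (site_id(target, res[0], int(res[1:])), "u" if data["sign"] == 1 else "d")
                )
        if members:
            signatures[kinase] = members
            categories[kinase] = category
    return SignatureDB(signatures=signatures, categories=categories)


def _downstream_edges(net: nx.DiGraph, target: str, max_hops: int = 2) -> list[tuple]:
    """Edges within ``max_hops`` downstream of ``target``: source at
    directed distance <= max_hops - 1 from the target kinase."""
    dist = nx.single_source_shortest_path_length(net, target, cutoff=max_hops - 1)
    return [(u, v) for u, v in net.edges if u in dist]


def gen_perturbation_dataset(
    net: nx.DiGraph,
    targets: list[str],
    effect_log2: float = 3.0,
    n_reps: int = 3,
    noise_sd: float = 0.1,
    seed: int = 0,
    n_fragments: int = 6,
    n_background_sites: int = 30,
    missing_rate: float = 0.03,
    sample: str = "S1",
) -> tuple[FragmentTable, GroundTruth]:
    """Fragment intensity table for simulated single-inhibitor treatments.

    One treatment condition ``<K>_inh`` per target kinase, plus a
    ``control`` condition, each with ``n_reps`` replicates. Every network
    edge residue yields a phosphopeptide (window around the site on the
    target protein) quantified by ``n_fragments`` fragments with log-normal
    baselines; ``n_background_sites`` additional unannotated sites add
    ranking background. Sites on edges within two hops downstream of a
    target are shifted by ``effect_log2`` with sign opposite the edge
    effect (inhibition pushes activating-edge sites down). Planted peptides
    get >= ``n_fragments`` fragments and elevated baselines so they survive
    the absolute-intensity and fragment-count filters.

    Fragments of one peptide share a per-column random effect with
    standard deviation ``2 * noise_sd`` on top of the per-value noise,
    mirroring the shared peptide-level variation across injections that
    makes real fragment profiles correlate; without it the consistency
    filter would discard fragments of unregulated peptides at random.
    """
    missing_targets = [t for t in targets if t not in net]
    if missing_targets:
        raise ValueError(f"target(s) not in network: {missing_targets}")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if effect_log2 == 0 and targets:
        warnings.warn("effect_log2 = 0: planted effects are null")
    rng = np.random.default_rng(seed)
    proteome = gen_proteome(net, seed=seed)

    # peptide catalog: one per annotated (edge, residue) site + background
    peptides = []  # (pep_id, protein, position, planted)
    for u, v, data in sorted(net.edges(data=True)):
        for res in sorted(data["residues"]):
            peptides.append((f"pep_{v}_{res}", v, int(res[1:]), True))
    bg_proteins = sorted(net.nodes)
    taken = {(p, pos) for _, p, pos, _ in peptides}
    added = 0
    while added < n_background_sites:
        prot = bg_proteins[int(rng.integers(0, len(bg_proteins)))]
        seq = proteome[prot]
        pos = int(rng.integers(1, len(seq) + 1))
        if (prot, pos) in taken:
            continue
        taken.add((prot, pos))
        peptides.append((f"pep_bg_{prot}_{pos}", prot, pos, False))
        added += 1

    conditions = ["control"] + [f"{t}_inh" for t in targets]
    columns = pd.MultiIndex.from_tuples(
        [(sample, c, r) for c in conditions for r in range(1, n_reps + 1)],
        names=["sample", "condition", "replicate"],
    )

    shifted: dict[str, dict[tuple[str, int], float]] = {}
    truth = GroundTruth(rng_seed=seed)
    for t in targets:
        cond = f"{t}_inh"
        truth.planted_target_kinases[cond] = t
        shifts: dict[tuple[str, int], float] = {}
        sites = set()
        for u, v in _downstream_edges(net, t):
            data = net[u][v]
            for res in sorted(data["residues"]):
                shifts[(v, int(res[1:]))] = -data["sign"] * effect_log2
                sites.add((v, res[0], int(res[1:])))
        shifted[cond] = shifts
        truth.planted_differential_sites[cond] = sites

    meta_rows = {}
    rows = []
    index = []
    for pep_id, prot, pos, planted in peptides:
        seq = proteome[prot]
        start = max(0, pos - 4)
        end = min(len(seq), pos + 3)
        meta_rows[pep_id] = {
            "protein": prot,
            "sequence": seq[start:end],
            "offsets": (pos - start,),
        }
        if planted:
            base_mu, base_sd = PLANTED_LOG2_MEAN, PLANTED_LOG2_SD
            n_frag = n_fragments
        else:
            base_mu, base_sd = BACKGROUND_LOG2_MEAN, BACKGROUND_LOG2_SD
            n_frag = int(rng.integers(5, n_fragments + 1))
        frag_base = rng.normal(base_mu, base_sd, size=n_frag)
        col_effect = rng.normal(0, 2 * noise_sd, size=len(columns))
        for f in range(n_frag):
            vals = []
            for k, (_, cond, _r) in enumerate(columns):
                shift = shifted.get(cond, {}).get((prot, pos), 0.0)
                vals.append(
                    2.0 ** (frag_base[f] + shift + col_effect[k] + rng.normal(0, noise_sd))
                )
            vals = np.array(vals)
            if missing_rate > 0 and not planted:
                vals[rng.random(len(vals)) < missing_rate] = np.nan
            rows.append(vals)
            index.append((pep_id, f"f{f}"))

    intensities = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["peptide", "fragment"]),
        columns=columns,
    )
    pep_meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    pep_meta.index.name = "peptide"
    return FragmentTable(intensities, pep_meta), truth


def gen_cell_map(
    n_cells: int,
    phenotype_props: dict[str, float],
    attract_pairs: list[tuple[str, str]] | None = None,
    strength: float = 0.0,
    frame_um: tuple[float, float] = (1000.0, 1000.0),
    seed: int = 0,
    roi_id: str = "ROI1",
    markers: dict | None = None,
    pattern: str = "cluster",
):
    """Spatial cell map with optional planted attraction pairs.

    Non-interacting phenotypes are placed uniformly at random (complete
    spatial randomness). For each planted pair ``(a, b)`` a fraction
    ``1 - exp(-strength / 2)`` of both the ``a`` and the ``b`` cells is
    rearranged; strength 0 reduces exactly to CSR and the aggregation
    saturates for large strength. Two placement patterns:

    - ``"cluster"`` (default): affected cells become daughters of shared,
      uniformly scattered cluster centers (isotropic Gaussian scatter,
      sigma = 12 um, Thomas-process style, ~15 daughters per cluster
      assigned round-robin so every cluster mixes both phenotypes) — broad
      co-aggregation of the pair.
    - ``"pair"``: affected ``b`` cells are placed in contact distance
      (sigma = 8 um) of individual ``a`` cells, one daughter per anchor
      where possible — many small heterotypic contacts, the regime in
      which checkpoint microaggregate counts exceed chance.

    Per-marker positive-area fractions default to one signature marker per
    phenotype, Beta(8, 2) on its own phenotype and Beta(1, 30) elsewhere;
    pass ``markers={name: {phenotype: (a, b)}}`` to override.
    """
    from crosstalk.spatial import CellMap

    if n_cells < 3:
        raise ValueError("need >= 3 cells for Voronoi geometry")
    props = dict(phenotype_props)
    if abs(sum(props.values()) - 1.0) > 1e-9:
        raise ValueError("phenotype proportions must sum to 1")
    if strength < 0:
        raise ValueError("strength must be >= 0")
    attract_pairs = list(attract_pairs or [])
    rng = np.random.default_rng(seed)
    w, h = frame_um

    # deterministic rounding of counts: floor + largest remainders
    names = sorted(props)
    raw = np.array([props[p] * n_cells for p in names])
    counts = np.floor(raw).astype(int)
    rem = n_cells - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1

    frac = 1.0 - np.exp(-strength / 2.0)

    positions: dict[str, np.ndarray] = {}
    for p, cnt in zip(names, counts):
        positions[p] = np.column_stack([rng.uniform(0, w, cnt), rng.uniform(0, h, cnt)])
    if pattern not in {"cluster", "pair"}:
        raise ValueError(f"unknown placement pattern {pattern!r}")
    for a, b in attract_pairs:
        if frac == 0:
            continue
        n_a = int(round(frac * len(positions.get(a, ()))))
        n_b = int(round(frac * len(positions.get(b, ()))))
        if n_a == 0 or n_b == 0:
            continue
        if pattern == "cluster":
            n_parents = max(3, (n_a + n_b) // 15)
            parents = np.column_stack(
                [rng.uniform(0, w, n_parents), rng.uniform(0, h, n_parents)]
            )
            for phen, n_d in ((a, n_a), (b, n_b)):
                # round-robin parent assignment: every cluster receives
                # both phenotypes in proportion, so the planted signal
                # does not fluctuate with the cluster composition draw
                pick = rng.permutation(np.arange(n_d) % n_parents)
                scatter = rng.normal(0, THOMAS_SIGMA_UM, size=(n_d, 2))
                positions[phen][:n_d] = np.clip(
                    parents[pick] + scatter, [0, 0], [w, h]
                )
        else:  # pair: one daughter next to one anchor where possible
            anchors = positions[a]
            pick = rng.permutation(np.arange(n_b) % len(anchors))
            scatter = rng.normal(0, 8.0, size=(n_b, 2))
            positions[b][:n_b] = np.clip(
                anchors[pick] + scatter, [0, 0], [w, h]
            )

    rows = []
    cid = 0
    for p in names:
        for x, y in positions[p]:
            rows.append({"cell_id": f"c{cid:04d}", "roi_id": roi_id, "x_um": x, "y_um": y, "phenotype": p})
            cid += 1
    cells = pd.DataFrame(rows)

    if markers is None:
        markers = {f"{p}_marker": {p: (8.0, 2.0)} for p in names}
    for mname, spec in markers.items():
        vals = np.empty(len(cells))
        for i, phen in enumerate(cells["phenotype"]):
            a, b = spec.get(phen, (1.0, 30.0))
            vals[i] = rng.beta(a, b)
        cells[mname] = vals

    truth = GroundTruth(
        rng_seed=seed,
        planted_attractions=set(attract_pairs) if strength > 0 else set(),
    )
    return CellMap(cells=cells, frame_um=frame_um), truth


def gen_mutations(
    net: nx.DiGraph, rate: float = 0.1, seed: int = 0, sample: str = "S1"
) -> pd.DataFrame:
    """Bernoulli coding-mutation gene list over the network's nodes."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [g for g in sorted(net.nodes) if rng.random() < rate]
    return pd.DataFrame({"sample": sample, "gene": genes})


def gen_complex_abundance(
    catalog: dict[str, list[str]],
    rho: float = 0.7,
    n_samples: int = 12,
    seed: int = 0,
    noise_complexes: list[str] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Equicorrelated log2 protein abundances per complex.

    Members of a complex share a latent per-sample factor:
    ``x = mu_m + sqrt(rho) * z_complex + sqrt(1 - rho) * eps``, giving
    pairwise correlation ``rho`` within the complex. Complexes listed in
    ``noise_complexes`` get rho = 0 (independent members); all complexes
    with rho > 0 are recorded as planted stable complexes.
    """
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    noise = set(noise_complexes or [])
    rows = {}
    truth = GroundTruth(rng_seed=seed)
    samples = [f"P{i:02d}" for i in range(n_samples)]
    for cid in sorted(catalog):
        r = 0.0 if cid in noise else rho
        z = rng.normal(size=n_samples)
        for member in catalog[cid]:
            mu = rng.normal(25.0, 2.0)
            eps = rng.normal(size=n_samples)
            rows[member] = mu + np.sqrt(r) * z + np.sqrt(1.0 - r) * eps
        if r > 0:
            truth.planted_stable_complexes.add(cid)
    m = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    m.index.name = "protein"
    return m, truth
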