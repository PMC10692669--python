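"""End-to-end orchestration with config, seeds and provenance capture.

``run`` executes the stages in dependency order — simulate (inputs),
phospho -> enrich -> network, with spatial and complexes independent — and
records every artifact in a manifest (path, SHA-256, parameters, seeds).
Stage seeds derive deterministically from the run seed, so a rerun with an
identical config reproduces every output bit-identically. With
``resume=True`` a stage is skipped when its recorded artifacts are intact
and the config hash matches.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from crosstalk import coabundance, enrichment, io, network, phospho, spatial, synth

logger = logging.getLogger(__name__)

_RANGES = {
    "node_fdr": (0.0, 1.0),
    "edge_fdr": (0.0, 1.0),
    "positivity": (0.0, 1.0),
    "p_thresh": (0.0, 1.0),
    "min_corr": (-1.0, 1.0),
    "edge_density": (0.0, 1.0),
    "noise_sd": (0.0, np.inf),
    "z_thresh": (0.0, np.inf),
    "strength": (0.0, np.inf),
    "rho": (0.0, 1.0),
}


@dataclass
class RunConfig:
    """All knobs of a pipeline run. Defaults equal the study's stated
    values where one exists (FDR 0.05, intensity 2000, 5 fragments,
    detection 2, SD factor 2, correlation 0.25, positivity 10%, 1000
    permutations, |Z| > 2, p < 0.01)."""

    seed: int = 0
    outdir: str = "run"
    # thresholds
    node_fdr: float = 0.05
    edge_fdr: float = 0.05
    log2fc_cut: float = 1.0
    min_intensity: float = 2000.0
    min_fragments: int = 5
    min_detected: int = 2
    sd_factor: float = 2.0
    min_corr: float = 0.25
    positivity: float = 0.10
    z_thresh: float = 2.0
    p_thresh: float = 0.01
    # permutation settings
    n_perm_enrich: int = 1000
    n_iter_spatial: int = 1000
    # synthetic-data sizes (the simulated study conditions)
    n_kinases: int = 12
    n_substrates: int = 25
    edge_density: float = 0.12
    n_targets: int = 2
    effect_log2: float = 3.0
    n_reps: int = 3
    noise_sd: float = 0.1
    n_cells: int = 500
    n_rois: int = 3
    strength: float = 5.0
    mutation_rate: float = 0.15
    n_complexes: int = 10
    complex_size: int = 6
    rho: float = 0.7
    n_samples: int = 12
    mrna_corr: float = 0.3

    def validate(self) -> None:
        for name, (lo, hi) in _RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"config field {name!r} = {v} outside [{lo}, {hi}]")
        if self.seed is None:
            raise ValueError("config field 'seed' is mandatory")
        for name in ("n_perm_enrich", "n_iter_spatial"):
            if getattr(self, name) < 100:
                raise ValueError(f"config field {name!r} must be >= 100")

    # round-trips unchanged through YAML
    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config field(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class Manifest:
    """Artifact registry for one run."""

    def __init__(self, outdir: Path, config: RunConfig):
        self.outdir = outdir
        self.data = {"config_hash": config.config_hash(), "stages": {}}

    def record(self, stage: str, artifacts: list[Path], params: dict) -> None:
        self.data["stages"][stage] = {
            "params": params,
            "artifacts": {
                str(p.relative_to(self.outdir)): _sha256(p) for p in artifacts
            },
        }

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True))
        return path

    def stage_intact(self, stage: str, previous: dict | None) -> bool:
        if not previous or previous.get("config_hash") != self.data["config_hash"]:
            return False
        rec = previous.get("stages", {}).get(stage)
        if not rec:
            return False
        for rel, digest in rec["artifacts"].items():
            p = self.outdir / rel
            if not p.exists() or _sha256(p) != digest:
                return False
        self.data["stages"][stage] = rec
        return True


def simulate(config: RunConfig, outdir: Path) -> dict:
    """Generate every pipeline input with ground-truth sidecars."""
    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    seed = config.stage_seed("simulate")
    rng = np.random.default_rng(seed)

    net = synth.gen_prior_network(
        config.n_kinases, config.n_substrates, config.edge_density, seed=seed
    )
    proteome = synth.gen_proteome(net, seed=seed)
    db = synth.gen_signature_db(net)
    kinases = sorted(n for n in net.nodes if net.out_degree(n) > 0)
    targets = [kinases[i] for i in rng.choice(len(kinases), size=min(config.n_targets, len(kinases)), replace=False)]
    frags, truth = synth.gen_perturbation_dataset(
        net,
        sorted(targets),
        effect_log2=config.effect_log2,
        n_reps=config.n_reps,
        noise_sd=config.noise_sd,
        seed=seed,
    )
    muts = synth.gen_mutations(net, rate=config.mutation_rate, seed=seed)

    io.write_prior_tsv(net, inputs / "prior_network.tsv")
    io.write_fasta(proteome, inputs / "proteome.fasta")
    io.write_gmt(db, inputs / "signatures.gmt")
    io.write_fragment_csv(frags, inputs / "fragments.csv")
    io.write_mutations_tsv(muts, inputs / "mutations.tsv")

    cell_paths = []
    for r in range(config.n_rois):
        cm, cm_truth = synth.gen_cell_map(
            config.n_cells,
            {"tumor": 0.4, "immune": 0.3, "stromal": 0.3},
            attract_pairs=[("tumor", "immune")],
            strength=config.strength,
            seed=seed + 1 + r,
            roi_id=f"ROI{r + 1}",
            markers={
                "PDL1": {"tumor": (6.0, 4.0)},
                "PD1": {"immune": (6.0, 4.0)},
                "keratin": {"tumor": (8.0, 2.0)},
                "CD45": {"immune": (8.0, 2.0)},
            },
        )
        path = inputs / f"cells_ROI{r + 1}.csv"
        io.write_cellmap_csv(cm, path)
        cell_paths.append(path)
        truth.planted_attractions |= cm_truth.planted_attractions

    catalog = {
        f"CPLX{i:02d}": [f"CPLX{i:02d}_SU{j}" for j in range(config.complex_size)]
        for i in range(config.n_complexes)
    }
    noise = sorted(catalog)[config.n_complexes // 2:]
    prot_matrix, cplx_truth = synth.gen_complex_abundance(
        catalog, rho=config.rho, n_samples=config.n_samples, seed=seed,
        noise_complexes=noise,
    )
    truth.planted_stable_complexes = cplx_truth.planted_stable_complexes
    # matched mRNA matrix with planted per-gene correlation
    r = config.mrna_corr
    eps = rng.normal(size=prot_matrix.shape)
    z = (prot_matrix - prot_matrix.mean(axis=1).to_numpy()[:, None])
    z = z / z.std(axis=1).to_numpy()[:, None]
    rna_matrix = 5.0 + r * z + np.sqrt(1 - r**2) * eps
    io.write_catalog_tsv(catalog, inputs / "complexes.tsv")
    io.write_abundance_csv(prot_matrix, inputs / "protein_abundance.csv")
    io.write_abundance_csv(rna_matrix, inputs / "rna_abundance.csv")
    io.write_ground_truth(truth, inputs / "ground_truth.json")

    artifacts = [
        inputs / "prior_network.tsv", inputs / "proteome.fasta",
        inputs / "signatures.gmt", inputs / "fragments.csv",
        inputs / "mutations.tsv", inputs / "complexes.tsv",
        inputs / "protein_abundance.csv", inputs / "rna_abundance.csv",
        inputs / "ground_truth.json", *cell_paths,
    ]
    return {"artifacts": artifacts, "seed": seed}


def run_phospho(config: RunConfig, outdir: Path) -> dict:
    inputs = outdir / "inputs"
    frags = io.read_fragment_csv(inputs / "fragments.csv")
    proteome = io.read_fasta(inputs / "proteome.fasta")
    filtered = phospho.filter_fragments(
        frags,
        min_intensity=config.min_intensity,
        min_fragments=config.min_fragments,
        min_detected_per_condition=config.min_detected,
        sd_factor=config.sd_factor,
        min_corr=config.min_corr,
    )
    imputed = phospho.impute_missing(filtered)
    site_map = phospho.map_sites(imputed, proteome)
    treatments = [c for c in imputed.conditions() if c != "control"]
    tables = [
        phospho.differential(imputed, t, "control", site_map) for t in treatments
    ]
    diff = pd.concat(tables, ignore_index=True)
    path = outdir / "differential_sites.csv"
    diff.to_csv(path, index=False)
    return {"artifacts": [path]}


def run_enrich(config: RunConfig, outdir: Path) -> dict:
    db = io.read_gmt(outdir / "inputs" / "signatures.gmt")
    diff = pd.read_csv(outdir / "differential_sites.csv")
    seed = config.stage_seed("enrich")
    results = []
    for t, sub in diff.groupby("treatment"):
        scores = enrichment.demultiplex(enrichment.score_sites(sub))
        res = enrichment.enrich(
            scores, db, n_perm=config.n_perm_enrich, seed=seed
        )
        res.insert(0, "treatment", t)
        results.append(res)
    out = pd.concat(results, ignore_index=True)
    path = outdir / "enrichment.csv"
    out.to_csv(path, index=False)
    return {"artifacts": [path], "seed": seed}


def run_network(config: RunConfig, outdir: Path) -> dict:
    inputs = outdir / "inputs"
    prior = network.load_prior(inputs / "prior_network.tsv")
    diff = pd.read_csv(outdir / "differential_sites.csv")
    enr = pd.read_csv(outdir / "enrichment.csv")
    muts = io.read_mutations_tsv(inputs / "mutations.tsv")

    subs = []
    artifacts = []
    for t in sorted(diff["treatment"].unique()):
        annotated = network.annotate(
            prior, enr[enr["treatment"] == t], diff[diff["treatment"] == t]
        )
        sub = network.extract_subnetwork(
            annotated,
            node_fdr=config.node_fdr,
            edge_fdr=config.edge_fdr,
            treatment=t,
        )
        sub = network.prune_redundant_paths(sub)
        if not sub.empty:
            gml = outdir / f"subnetwork_{t}.graphml"
            csv = outdir / f"subnetwork_{t}_edges.csv"
            io.write_subnetwork(sub, gml, csv)
            artifacts += [gml, csv]
            subs.append(sub)

    summary: dict = {"treatments": [s.treatment for s in subs]}
    if subs:
        for s in subs:  # merged network needs one shared parent structure
            s.parent = prior
        merged = network.merge_subnetworks(subs)
        cent = network.centralities(merged)
        cent_path = outdir / "centralities.csv"
        cent.to_csv(cent_path, index=False)
        artifacts.append(cent_path)
        fisher = network.mutation_enrichment(merged, prior, set(muts["gene"]))
        summary["fisher"] = {
            "table": fisher.table.tolist(),
            "odds_ratio": None if np.isnan(fisher.odds_ratio) else fisher.odds_ratio,
            "pvalue": fisher.pvalue,
        }
        gml = outdir / "subnetwork_merged.graphml"
        csv = outdir / "subnetwork_merged_edges.csv"
        io.write_subnetwork(merged, gml, csv)
        artifacts += [gml, csv]
    summary_path = outdir / "network_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    artifacts.append(summary_path)
    return {"artifacts": artifacts}


def run_spatial(config: RunConfig, outdir: Path) -> dict:
    inputs = outdir / "inputs"
    seed = config.stage_seed("spatial")
    rows = []
    agg_rows = []
    for k, path in enumerate(sorted(inputs.glob("cells_*.csv"))):
        cm = io.read_cellmap_csv(path)
        roi = cm.cells["roi_id"].iloc[0]
        g = spatial.voronoi_neighbors(cm)
        labels = cm.cells.set_index("cell_id")["phenotype"]
        res = spatial.interaction_test(
            g, labels, n_iter=config.n_iter_spatial, seed=seed + k,
            z_thresh=config.z_thresh, p_thresh=config.p_thresh,
        )
        res.insert(0, "roi_id", roi)
        dens = spatial.densities(cm)
        res["density_a"] = res["phenotype_a"].map(dens)
        rows.append(res)
        pdl1 = spatial.marker_positive(cm, "PDL1", config.positivity) & (
            cm.cells.set_index("cell_id")["phenotype"] == "tumor"
        )
        pd1 = spatial.marker_positive(cm, "PD1", config.positivity) & (
            cm.cells.set_index("cell_id")["phenotype"] == "immune"
        )
        aggs = spatial.microaggregates(g, pdl1, pd1)
        z, p = spatial.microaggregate_test(
            g, pdl1, pd1, n_iter=config.n_iter_spatial, seed=seed + 1000 + k
        )
        agg_rows.append(
            {"roi_id": roi, "n_microaggregates": len(aggs), "z": z, "pvalue": p}
        )
    per_roi = pd.concat(rows, ignore_index=True)
    cohort = (
        per_roi.dropna(subset=["z"])
        .groupby(["phenotype_a", "phenotype_b"])["z"]
        .apply(lambda zs: spatial.stouffer_combine(list(zs)))
        .rename("stouffer_z")
        .reset_index()
    )
    p1 = outdir / "spatial_interactions.csv"
    p2 = outdir / "spatial_cohort.csv"
    p3 = outdir / "microaggregates.csv"
    per_roi.to_csv(p1, index=False)
    cohort.to_csv(p2, index=False)
    pd.DataFrame(agg_rows).to_csv(p3, index=False)
    return {"artifacts": [p1, p2, p3], "seed": seed}


def run_complexes(config: RunConfig, outdir: Path) -> dict:
    inputs = outdir / "inputs"
    catalog = io.read_catalog_tsv(inputs / "complexes.tsv")
    prot = io.read_abundance_csv(inputs / "protein_abundance.csv")
    rna = io.read_abundance_csv(inputs / "rna_abundance.csv")
    stability = coabundance.complex_coabundance(prot, catalog, min_members=5)
    corr = coabundance.gene_wise_correlation(rna, prot, min_samples=4)
    p1 = outdir / "complex_stability.csv"
    p2 = outdir / "mrna_protein_correlation.csv"
    stability.to_csv(p1, index=False)
    corr.rename_axis("gene").to_csv(p2)
    return {"artifacts": [p1, p2]}


_STAGES = [
    ("simulate", simulate),
    ("phospho", run_phospho),
    ("enrich", run_enrich),
    ("network", run_network),
    ("spatial", run_spatial),
    ("complexes", run_complexes),
]


def run(config: RunConfig, resume: bool = False) -> Path:
    """Execute all stages in dependency order; returns the manifest path."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(outdir, config)
    previous = None
    prev_path = outdir / "manifest.json"
    if resume and prev_path.exists():
        previous = json.loads(prev_path.read_text())
    for name, fn in _STAGES:
        if resume and manifest.stage_intact(name, previous):
            logger.info("stage %s intact; skipped", name)
            continue
        logger.info("running stage %s", name)
        result = fn(config, outdir)
        params = {"seed": result.get("seed", config.seed)}
        manifest.record(name, result["artifacts"], params)
    config.to_yaml(outdir / "config.yaml")
    return manifest.write()
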