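"""In-memory convenience workflows chaining the analysis stages.

These are the library-level counterparts of the CLI pipeline: generate or
accept inputs, run fragment processing, enrichment and subnetwork
extraction in one call, and return every intermediate. Used by the
examples and the validation scripts; all knobs default to the pipeline's
standard thresholds.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from crosstalk import enrichment, network, phospho, synth


def analyze_perturbation(
    net: nx.DiGraph,
    targets: list[str],
    seed: int,
    effect_log2: float = 3.0,
    noise_sd: float = 0.1,
    n_reps: int = 3,
    n_perm: int = 1000,
    node_fdr: float = 0.05,
    edge_fdr: float = 0.05,
) -> dict:
    """Simulate inhibitor perturbations on ``net`` and run the full
    phospho -> enrichment -> subnetwork chain.

    Returns a dict with the fragment table, differential site table,
    per-treatment enrichment results, pruned subnetworks and the planted
    ground truth.
    """
    frags, truth = synth.gen_perturbation_dataset(
        net, targets, effect_log2=effect_log2, noise_sd=noise_sd,
        n_reps=n_reps, seed=seed,
    )
    proteome = synth.gen_proteome(net, seed=seed)
    db = synth.gen_signature_db(net)

    imputed = phospho.impute_missing(phospho.filter_fragments(frags))
    site_map = phospho.map_sites(imputed, proteome)
    treatments = [c for c in imputed.conditions() if c != "control"]

    diffs, enrichments, subnetworks = [], {}, {}
    for k, t in enumerate(treatments):
        d = phospho.differential(imputed, t, "control", site_map)
        diffs.append(d)
        scores = enrichment.demultiplex(enrichment.score_sites(d))
        res = enrichment.enrich(scores, db, n_perm=n_perm, seed=seed + k)
        enrichments[t] = res
        annotated = network.annotate(net, res, d)
        sub = network.extract_subnetwork(
            annotated, node_fdr=node_fdr, edge_fdr=edge_fdr, treatment=t
        )
        subnetworks[t] = network.prune_redundant_paths(sub)

    return {
        "fragments": frags,
        "truth": truth,
        "diff": pd.concat(diffs, ignore_index=True) if diffs else pd.DataFrame(),
        "enrichment": enrichments,
        "subnetworks": subnetworks,
    }


def site_recovery(diff: pd.DataFrame, planted: set, log2fc_cut: float = 1.0,
                  fdr_cut: float = 0.05) -> tuple[int, int]:
    """(recovered, planted) counts of planted sites passing the
    |log2FC| > cut & FDR < cut gate."""
    hit = 0
    for p, _r, q in planted:
        ok = (
            (diff["protein"] == p)
            & (diff["position"] == q)
            & (diff["log2fc"].abs() > log2fc_cut)
            & (diff["fdr"] < fdr_cut)
        )
        hit += bool(ok.any())
    return hit, len(planted)
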