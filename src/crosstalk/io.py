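"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: long-format fragment CSV, SIGNOR-style TSV for
the prior network, GMT-style signature files with per-site direction flags
(elements are ``ACC;RES+POS;direction``, e.g. ``AKT1;S473;u``), FASTA for
the proteome, cell-table CSV, two-column mutation TSV, abundance CSV and a
ground-truth JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from crosstalk.enrichment import SignatureDB
from crosstalk.phospho import FragmentTable
from crosstalk.spatial import CellMap
from crosstalk.synth import GroundTruth


# -- fragment tables ---------------------------------------------------------

def write_fragment_csv(t: FragmentTable, path) -> None:
    long = t.intensities.stack(["sample", "condition", "replicate"], future_stack=True)
    long = long.rename("intensity").reset_index()
    meta = t.peptides.copy()
    meta["phospho_offsets"] = meta["offsets"].map(lambda o: ";".join(str(i) for i in o))
    long = long.merge(
        meta[["protein", "sequence", "phospho_offsets"]],
        left_on="peptide",
        right_index=True,
    )
    long.to_csv(path, index=False)


def read_fragment_csv(path) -> FragmentTable:
    long = pd.read_csv(path)
    wide = long.pivot(
        index=["peptide", "fragment"],
        columns=["sample", "condition", "replicate"],
        values="intensity",
    )
    meta = (
        long[["peptide", "protein", "sequence", "phospho_offsets"]]
        .drop_duplicates("peptide")
        .set_index("peptide")
    )
    meta["offsets"] = meta.pop("phospho_offsets").map(
        lambda s: tuple(int(i) for i in str(s).split(";"))
    )
    return FragmentTable(wide, meta)


# -- prior network -----------------------------------------------------------

def write_prior_tsv(net: nx.DiGraph, path) -> None:
    rows = [
        {
            "ENTITYA": u,
            "ENTITYB": v,
            "EFFECT": "up-regulates" if d["sign"] == 1 else "down-regulates",
            "MECHANISM": d.get("mechanism", "phosphorylation"),
            "RESIDUE": ";".join(sorted(d["residues"])),
        }
        for u, v, d in sorted(net.edges(data=True))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- signatures (GMT-style) --------------------------------------------------

def write_gmt(db: SignatureDB, path) -> None:
    with open(path, "w") as fh:
        for name, members in db.signatures.items():
            cat = db.categories.get(name, "KINASE")
            elements = "\t".join(f"{sid};{d}" for sid, d in members)
            fh.write(f"{name}\t{cat}\t{elements}\n")


def read_gmt(path) -> SignatureDB:
    signatures: dict = {}
    categories: dict = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, cat, elements = parts[0], parts[1], parts[2:]
            members = []
            for el in elements:
                acc, res, direction = el.rsplit(";", 2)
                members.append((f"{acc};{res}", direction))
            signatures[name] = members
            categories[name] = cat
    return SignatureDB(signatures=signatures, categories=categories)


# -- proteome ----------------------------------------------------------------

def write_fasta(proteome: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=acc, description="") for acc, seq in proteome.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


# -- cell maps ---------------------------------------------------------------

def write_cellmap_csv(c: CellMap, path) -> None:
    df = c.cells.copy()
    df["frame_w_um"], df["frame_h_um"] = c.frame_um
    df.to_csv(path, index=False)


def read_cellmap_csv(path) -> CellMap:
    df = pd.read_csv(path)
    frame = (float(df["frame_w_um"].iloc[0]), float(df["frame_h_um"].iloc[0]))
    return CellMap(df.drop(columns=["frame_w_um", "frame_h_um"]), frame_um=frame)


# -- small tables ------------------------------------------------------------

def write_mutations_tsv(df: pd.DataFrame, path) -> None:
    df[["sample", "gene"]].to_csv(path, sep="\t", index=False)


def read_mutations_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_abundance_csv(m: pd.DataFrame, path) -> None:
    m.to_csv(path)


def read_abundance_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_catalog_tsv(catalog: dict[str, list[str]], path) -> None:
    rows = [(cid, member) for cid in sorted(catalog) for member in catalog[cid]]
    pd.DataFrame(rows, columns=["complex", "member"]).to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {cid: list(sub["member"]) for cid, sub in df.groupby("complex")}


# -- ground truth sidecar ----------------------------------------------------

def write_ground_truth(gt: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(gt.to_dict(), indent=2, sort_keys=True))


def read_ground_truth(path) -> dict:
    return json.loads(Path(path).read_text())


# -- subnetwork export -------------------------------------------------------

def _scalarize(value):
    if isinstance(value, (set, frozenset, tuple, list)):
        return ";".join(str(v) for v in sorted(value))
    return value


def write_subnetwork(sub, graphml_path, edges_csv_path) -> None:
    """GraphML plus a flat edge-list CSV with attributes and provenance."""
    g = sub.graph.copy()
    for n, d in g.nodes(data=True):
        for k in list(d):
            d[k] = _scalarize(d[k])
        d["provenance"] = ";".join(sorted(sub.node_provenance.get(n, set())))
    rows = []
    for u, v, d in g.edges(data=True):
        for k in list(d):
            d[k] = _scalarize(d[k])
        d["provenance"] = ";".join(sorted(sub.edge_provenance.get((u, v), set())))
        rows.append({"source": u, "target": v, **d})
    nx.write_graphml(g, graphml_path)
    pd.DataFrame(rows).to_csv(edges_csv_path, index=False)
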