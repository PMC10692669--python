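"""Protein-complex co-abundance and mRNA-protein correlation.

Protein complexes tend to keep their subunits at correlated abundances
across samples; ranking complexes by the mean pairwise Pearson correlation
of their measured members separates *stable* complexes (coordinated
subunits, top quartile of the ranking) from *variable* ones (bottom
quartile). Subunit variance highlights individual members that escape the
complex-level coordination, and gene-wise Pearson correlation between
matched mRNA and protein abundance matrices quantifies how well transcript
levels predict protein levels.

All matrices are features x samples, log2 scale, with missing values
allowed; correlations use pairwise-complete observations.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _pairwise_corr(x: pd.DataFrame, min_shared: int = 3) -> list[float]:
    """Pearson correlations for all row pairs, pairwise-complete.

    Pairs with fewer than ``min_shared`` shared samples, or with a
    zero-variance profile, are skipped (logged at debug level).
    """
    vals = x.to_numpy(float)
    out: list[float] = []
    n = len(vals)
    for i in range(n):
        for j in range(i + 1, n):
            mask = ~np.isnan(vals[i]) & ~np.isnan(vals[j])
            if mask.sum() < min_shared:
                logger.debug("pair (%s, %s): <%d shared samples, skipped", x.index[i], x.index[j], min_shared)
                continue
            a, b = vals[i][mask], vals[j][mask]
            if a.std() == 0 or b.std() == 0:
                continue
            out.append(float(np.corrcoef(a, b)[0, 1]))
    return out


def complex_coabundance(
    m: pd.DataFrame, catalog: dict[str, list[str]], min_members: int = 5
) -> pd.DataFrame:
    """Rank protein complexes by member co-abundance.

    Complexes with fewer than ``min_members`` measured members are
    excluded. Each retained complex is scored by the mean of all pairwise
    member Pearson correlations (pairwise-complete observations; pairs
    sharing fewer than 3 samples are skipped). Quartile classes on the
    ranked list: the ceil(N/4) highest-scoring complexes are ``stable``,
    the ceil(N/4) lowest-scoring (among the rest) are ``variable``, the
    middle is ``intermediate``. Ties in score break deterministically by
    complex id.
    """
    if min_members < 2:
        raise ValueError("min_members must be >= 2")
    rows = []
    for cid in sorted(catalog):
        members = [p for p in dict.fromkeys(catalog[cid]) if p in m.index]
        if len(members) < min_members:
            continue
        corrs = _pairwise_corr(m.loc[members])
        if not corrs:
            logger.info("complex %s has no valid member pair; excluded", cid)
            continue
        rows.append({"complex": cid, "score": float(np.mean(corrs)), "n_members": len(members)})
    out = pd.DataFrame(rows, columns=["complex", "score", "n_members"])
    if out.empty:
        out["rank"] = pd.Series(dtype=int)
        out["class"] = pd.Series(dtype=object)
        return out
    out = out.sort_values(["score", "complex"], ascending=[False, True], kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    n = len(out)
    tail = math.ceil(n / 4)
    cls = np.array(["intermediate"] * n, dtype=object)
    cls[:tail] = "stable"
    cls[max(tail, n - tail):] = "variable"
    out["class"] = cls
    return out


def subunit_variance(m: pd.DataFrame, members: list[str]) -> pd.Series:
    """Per-member sample variance over observed values (n-1 denominator).

    Members with fewer than two observed values get a missing variance
    (logged).
    """
    missing = [p for p in members if p not in m.index]
    if missing:
        raise KeyError(f"member(s) absent from matrix: {', '.join(missing)}")
    sub = m.loc[members]
    n_obs = sub.notna().sum(axis=1)
    var = sub.var(axis=1, ddof=1)
    low = n_obs < 2
    if low.any():
        logger.info("%d member(s) with <2 observations; variance missing", int(low.sum()))
        var[low] = np.nan
    return var


def gene_wise_correlation(
    rna: pd.DataFrame, prot: pd.DataFrame, min_samples: int = 4
) -> pd.Series:
    """Per-gene Pearson correlation between mRNA and protein abundance.

    Samples are matched by name; genes need at least ``min_samples`` paired
    observations, others are excluded. Raises when the matrices share no
    samples.
    """
    shared_samples = [s for s in rna.columns if s in set(prot.columns)]
    if not shared_samples:
        raise ValueError("mRNA and protein matrices share no samples")
    shared_genes = rna.index.intersection(prot.index)
    r = rna.loc[shared_genes, shared_samples].to_numpy(float)
    p = prot.loc[shared_genes, shared_samples].to_numpy(float)
    out = {}
    for k, gene in enumerate(shared_genes):
        mask = ~np.isnan(r[k]) & ~np.isnan(p[k])
        if mask.sum() < min_samples:
            continue
        a, b = r[k][mask], p[k][mask]
        if a.std() == 0 or b.std() == 0:
            continue
        out[gene] = float(np.corrcoef(a, b)[0, 1])
    return pd.Series(out, name="pearson_r", dtype=float)
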