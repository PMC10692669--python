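"""Fragment-level phosphoproteomic processing and differential abundance.

The quantitative unit coming off a DIA/SWATH experiment is the *fragment*:
an MS2 product ion whose intensity quantifies a phosphopeptide, with several
fragments per peptide. This module filters fragments, imputes missing
replicate values, rolls fragments up to peptides, maps peptides to
protein-level phosphosites, and computes per-treatment differential
abundance (log2 fold change vs. control, Student t-test, Benjamini-Hochberg
FDR across sites).

Conventions
-----------
- Intensities are linear and non-negative; all log transforms are base 2.
- A phosphosite key is ``(protein, residue, position, multiplicity)`` with a
  1-based protein position; the residue letter is taken from the protein
  sequence (authoritative over the peptide annotation; conflicts logged).
- The absolute intensity prefilter keeps values strictly above the
  threshold (2000 by default).
- Filter order is fixed and recorded in provenance: absolute intensity ->
  per-condition detection count -> correlation/outlier consistency ->
  minimum fragments per peptide.

The differential engine is deliberately simple and transparent
(summed-fragment rollup + two-sample t-test + BH); its name and parameters
are recorded in the output ``attrs`` so downstream consumers know which
statistic produced the numbers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Column order of the long-format fragment CSV.
FRAGMENT_COLUMNS = [
    "peptide",
    "fragment",
    "sample",
    "condition",
    "replicate",
    "intensity",
]

SITE_KEY = ["protein", "residue", "position", "multiplicity"]


@dataclass
class FragmentTable:
    """Fragment intensities plus peptide metadata.

    Attributes
    ----------
    intensities
        Wide matrix with a ``(peptide, fragment)`` row MultiIndex and a
        ``(sample, condition, replicate)`` column MultiIndex. ``NaN`` marks
        a missing (undetected) value.
    peptides
        Per-peptide metadata indexed by peptide id with columns
        ``protein`` (accession), ``sequence`` (peptide sequence) and
        ``offsets`` (tuple of 1-based phospho-residue offsets within the
        peptide).
    """

    intensities: pd.DataFrame
    peptides: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.intensities.to_numpy(dtype=float)
        if vals.size and not np.isnan(vals).all() and np.nanmin(vals) < 0:
            raise ValueError("fragment intensities must be non-negative")
        if self.intensities.index.nlevels != 2:
            raise ValueError("intensities need a (peptide, fragment) row index")
        if self.intensities.columns.nlevels != 3:
            raise ValueError(
                "intensities need (sample, condition, replicate) columns"
            )

    @property
    def empty(self) -> bool:
        return self.intensities.empty

    def conditions(self) -> list[str]:
        return list(
            dict.fromkeys(self.intensities.columns.get_level_values("condition"))
        )

    def copy(self) -> "FragmentTable":
        return FragmentTable(self.intensities.copy(), self.peptides.copy())

    def _replace(self, intensities: pd.DataFrame) -> "FragmentTable":
        kept = intensities.index.get_level_values(0).unique()
        return FragmentTable(intensities, self.peptides.loc[self.peptides.index.intersection(kept)])


def filter_fragments(
    t: FragmentTable,
    min_intensity: float = 2000.0,
    min_fragments: int = 5,
    min_detected_per_condition: int = 2,
    sd_factor: float = 2.0,
    min_corr: float = 0.25,
) -> FragmentTable:
    """Prefilter fragment intensities for reliable quantification.

    Four gates, applied in this order (the order is part of the contract):

    1. *Absolute intensity*: values ``<= min_intensity`` become missing
       (only intensities strictly above the threshold are trusted).
    2. *Detection count*: a fragment must be detected at least
       ``min_detected_per_condition`` times in at least one condition;
       otherwise it is dropped.
    3. *Consistency*: within each peptide, a fragment is dropped when its
       log2 profile correlates below ``min_corr`` with the peptide's median
       fragment profile, or when its mean log2 intensity deviates from the
       peptide consensus by more than ``sd_factor`` standard deviations of
       the fragment means. Both rules are evaluated on the pre-drop set so
       a single pass is deterministic.
    4. *Fragment count*: peptides left with fewer than ``min_fragments``
       fragments are dropped entirely.

    An empty table passes through unchanged; a table whose every fragment is
    removed returns empty with a warning.
    """
    for name, v in [
        ("min_intensity", min_intensity),
        ("min_fragments", min_fragments),
        ("min_detected_per_condition", min_detected_per_condition),
        ("sd_factor", sd_factor),
        ("min_corr", min_corr),
    ]:
        if name != "min_corr" and v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    if t.empty:
        return t.copy()

    x = t.intensities.where(t.intensities > min_intensity)

    # detection per condition over (sample, replicate)
    detected = x.notna().T.groupby(level="condition").sum().T
    keep = detected.max(axis=1) >= min_detected_per_condition
    x = x.loc[keep]

    if not x.empty:
        logx = np.log2(x)
        drop: list[tuple] = []
        for pep, block in logx.groupby(level=0, sort=False):
            if len(block) < 2:
                continue
            consensus = block.median(axis=0)
            means = block.mean(axis=1)
            mu, sd = means.mean(), means.std(ddof=1)
            for idx, row in block.iterrows():
                shared = row.notna() & consensus.notna()
                if shared.sum() >= 3:
                    a = row[shared].to_numpy()
                    b = consensus[shared].to_numpy()
                    if a.std() > 0 and b.std() > 0:
                        r = float(np.corrcoef(a, b)[0, 1])
                        if r < min_corr:
                            drop.append(idx)
                            continue
                if len(block) >= 3 and sd > 0 and abs(means[idx] - mu) > sd_factor * sd:
                    drop.append(idx)
        if drop:
            logger.info("consistency filter removed %d fragments", len(drop))
            x = x.drop(index=drop)

    if not x.empty:
        n_frag = x.groupby(level=0, sort=False).size()
        good = n_frag[n_frag >= min_fragments].index
        x = x.loc[x.index.get_level_values(0).isin(good)]

    if x.empty and not t.empty:
        warnings.warn("all fragments removed by filtering; returning empty table")
    return t._replace(x)


def impute_missing(t: FragmentTable) -> FragmentTable:
    """Replace missing replicate values per fragment by 20% of that
    fragment's minimum observed intensity.

    Observed values are never altered. Fragments with no observed value at
    all cannot be imputed and are dropped with a warning.
    """
    if t.empty:
        return t.copy()
    x = t.intensities
    n_obs = x.notna().sum(axis=1)
    dead = n_obs == 0
    if dead.any():
        warnings.warn(
            f"dropping {int(dead.sum())} fragment(s) with no observed value"
        )
        x = x.loc[~dead]
    floor = 0.2 * x.min(axis=1)
    x = x.apply(lambda col: col.fillna(floor))
    return t._replace(x)


def map_sites(t: FragmentTable, proteome: dict[str, str]) -> pd.DataFrame:
    """Locate each peptide's phospho-residues on its protein sequence.

    Returns a site map with one row per (peptide, phosphosite): columns
    ``peptide, protein, residue, position, multiplicity``. Positions are
    1-based on the protein; multiplicity is the number of phospho-residues
    on the peptide. Peptides not found in their stated protein are excluded
    (logged); peptides occurring more than once use the first occurrence
    (flagged in the log). The residue letter is read off the protein
    sequence; a conflicting peptide annotation is logged and overridden.
    """
    rows = []
    for pep, meta in t.peptides.iterrows():
        seq = proteome.get(meta["protein"])
        if seq is None:
            logger.warning("protein %s absent from proteome; peptide %s excluded", meta["protein"], pep)
            continue
        start = seq.find(meta["sequence"])
        if start < 0:
            logger.warning("peptide %s not found in %s; excluded", pep, meta["protein"])
            continue
        if seq.find(meta["sequence"], start + 1) >= 0:
            logger.warning(
                "peptide %s occurs multiple times in %s; first occurrence used",
                pep,
                meta["protein"],
            )
        offsets = tuple(meta["offsets"])
        for off in offsets:
            pos = start + off  # 1-based protein position
            residue = seq[pos - 1]
            if meta["sequence"][off - 1] != residue:
                logger.warning(
                    "residue conflict for %s at %s%d; protein sequence wins",
                    pep,
                    residue,
                    pos,
                )
            rows.append(
                {
                    "peptide": pep,
                    "protein": meta["protein"],
                    "residue": residue,
                    "position": pos,
                    "multiplicity": len(offsets),
                }
            )
    return pd.DataFrame(rows, columns=["peptide"] + SITE_KEY)


def collapse_duplicate_sites(d: pd.DataFrame) -> pd.DataFrame:
    """Keep one record per phosphosite key.

    When several peptides map to the same site, the record with the highest
    mean control signal wins; exact ties fall to the lexicographically
    smallest peptide id.
    """
    if d.empty:
        return d.copy()
    keys = [c for c in ["treatment"] + SITE_KEY if c in d.columns]
    out = (
        d.sort_values(["mean_control", "peptide"], ascending=[False, True], kind="mergesort")
        .drop_duplicates(subset=keys, keep="first")
        .sort_values(keys, kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def _peptide_signal(x: pd.DataFrame) -> pd.DataFrame:
    """Sum fragment intensities per peptide per column."""
    return x.groupby(level=0, sort=False).sum(min_count=1)


def differential(
    t: FragmentTable,
    treatment: str,
    control: str,
    site_map: pd.DataFrame,
) -> pd.DataFrame:
    """Per-site differential abundance of ``treatment`` vs ``control``.

    Fragments are summed to a per-peptide signal per (sample, replicate)
    column; log2 signals are compared by a two-sample Student t-test, and
    log2FC is the difference of group means. Peptide statistics are mapped
    to sites via ``site_map`` (from :func:`map_sites`), duplicate sites
    collapsed by control signal, and BH adjustment applied across sites
    within the treatment.

    Both groups need >= 2 replicate columns. A peptide with zero variance
    in both groups gets p = 1 when the means are equal (and p = 0 on exact
    separation, a degenerate case only synthetic noise-free data produces).
    """
    cond = t.intensities.columns.get_level_values("condition")
    cols_t = t.intensities.columns[cond == treatment]
    cols_c = t.intensities.columns[cond == control]
    if len(cols_t) < 2 or len(cols_c) < 2:
        raise ValueError(
            f"need >= 2 replicates per group; got {len(cols_t)} for "
            f"{treatment!r} and {len(cols_c)} for {control!r}"
        )
    sig = _peptide_signal(t.intensities)
    log_t = np.log2(sig[cols_t])
    log_c = np.log2(sig[cols_c])
    lfc = log_t.mean(axis=1) - log_c.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tt = stats.ttest_ind(log_t, log_c, axis=1)
    pvals = pd.Series(tt.pvalue, index=sig.index)
    flat = pvals.isna()
    if flat.any():  # zero variance in both groups
        equal = lfc[flat].abs() < 1e-12
        pvals.loc[flat] = np.where(equal, 1.0, 0.0)
    mean_control = sig[cols_c].mean(axis=1)

    stats_df = pd.DataFrame(
        {
            "peptide": sig.index,
            "log2fc": lfc.to_numpy(),
            "pvalue": pvals.to_numpy(),
            "mean_control": mean_control.to_numpy(),
        }
    )
    d = site_map.merge(stats_df, on="peptide", how="inner")
    d["treatment"] = treatment
    d = collapse_duplicate_sites(d)
    if not d.empty:
        d["fdr"] = multipletests(d["pvalue"].to_numpy(), method="fdr_bh")[1]
    else:
        d["fdr"] = pd.Series(dtype=float)
    d = d[["treatment"] + SITE_KEY + ["peptide", "log2fc", "pvalue", "fdr", "mean_control"]]
    d.attrs["engine"] = "summed-fragment rollup + Student t-test + BH"
    d.attrs["filter_order"] = "intensity,detection,consistency,fragment_count"
    return d
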