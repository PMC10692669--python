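"""Site-centric signed signature enrichment (PTM-SEA-style).

Kinase and pathway activities are inferred from phosphosite statistics by a
running-sum enrichment over directional signature sets. Each measured site
carries a signed score — sign of the log2 fold change times the
-log10-transformed FDR — and each signature lists member sites with an
expected direction (``u`` up, ``d`` down). Down-direction members enter
with flipped sign, so a signature whose sites all move the expected way
under kinase inhibition produces a large-magnitude enrichment score.

The test statistic is the *area under the running enrichment statistic*:
sites are ranked by descending (direction-adjusted) score; members
increment the running sum by their normalized ``|score|**weight`` and
non-members decrement it uniformly; the ES is the mean of the running sum
over all rank positions. The classic maximum-deviation ES is available via
``statistic="max"``. Significance comes from site-label permutations:
NES = ES / mean(|ES_perm|) among same-sign permuted scores, and the p value
is the same-sign tail fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from crosstalk.phospho import SITE_KEY

_DIRECTIONS = {"u": "u", "up": "u", "d": "d", "down": "d"}


def site_id(protein: str, residue: str, position: int) -> str:
    """Canonical site identifier, e.g. ``"AKT1;S473"``."""
    return f"{protein};{residue}{int(position)}"


@dataclass
class SignatureDB:
    """Directional phosphosite signature sets.

    ``signatures`` maps a signature name to a list of ``(site_id,
    direction)`` pairs with direction in ``{"u", "d"}``; ``categories``
    assigns each signature to one of ``KINASE``, ``PERT`` or ``PATH``.
    """

    signatures: dict[str, list[tuple[str, str]]]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.signatures.items():
            norm = []
            seen = set()
            for sid, direction in members:
                if direction not in _DIRECTIONS:
                    raise ValueError(
                        f"signature {name!r}: direction {direction!r} not in u/d"
                    )
                if sid in seen:
                    raise ValueError(f"signature {name!r}: duplicate site {sid!r}")
                seen.add(sid)
                norm.append((sid, _DIRECTIONS[direction]))
            self.signatures[name] = norm

    def __len__(self) -> int:
        return len(self.signatures)


def score_sites(d: pd.DataFrame, fdr_floor: float = 1e-10) -> pd.DataFrame:
    """Signed site scores from a differential table.

    score = sign(log2FC) * -log10(max(FDR, fdr_floor)); a zero fold change
    scores exactly zero. The floor keeps scores finite when the adjusted p
    underflows.
    """
    if fdr_floor <= 0:
        raise ValueError("fdr_floor must be > 0")
    out = d.copy()
    mag = -np.log10(np.maximum(out["fdr"].to_numpy(dtype=float), fdr_floor))
    out["score"] = np.sign(out["log2fc"].to_numpy()) * mag
    keep = [c for c in ["treatment"] + SITE_KEY + ["score"] if c in out.columns]
    return out[keep].reset_index(drop=True)


def demultiplex(scores: pd.DataFrame) -> pd.DataFrame:
    """Expand multiply-phosphorylated records to single-site records.

    Each record with multiplicity > 1 becomes a multiplicity-1 record per
    constituent site, carrying the parent score. When an expanded record
    collides with an existing single-site record the larger ``|score|``
    wins (ties keep the pre-existing single-site record).
    """
    out = scores.copy()
    out["multiplicity"] = 1
    out["_rank"] = out["score"].abs()
    # stable sort: larger |score| first; on ties the original single-site
    # record (multiplicity 1 in the input) comes first
    out["_was_single"] = (scores["multiplicity"] == 1).astype(int)
    keys = [c for c in ["treatment", "protein", "residue", "position"] if c in out.columns]
    out = (
        out.sort_values(["_rank", "_was_single"], ascending=[False, False], kind="mergesort")
        .drop_duplicates(subset=keys, keep="first")
        .sort_values(keys, kind="mergesort")
        .drop(columns=["_rank", "_was_single"])
        .reset_index(drop=True)
    )
    return out


def _running_es(adjusted: np.ndarray, hit: np.ndarray, weight: float, statistic: str) -> np.ndarray:
    """Vectorized ES over rows of (adjusted score, hit) matrices.

    ``adjusted`` and ``hit`` are (k, N); each row is sorted by descending
    adjusted score before the running sum is accumulated.
    """
    order = np.argsort(-adjusted, axis=1, kind="stable")
    a = np.take_along_axis(adjusted, order, axis=1)
    h = np.take_along_axis(hit, order, axis=1)
    aw = np.abs(a) ** weight
    num = np.where(h, aw, 0.0)
    denom = num.sum(axis=1, keepdims=True)
    n_miss = (~h).sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        inc = num / denom - np.where(h, 0.0, 1.0) / n_miss
    res = np.cumsum(inc, axis=1)
    if statistic == "area":
        es = res.mean(axis=1)
    elif statistic == "max":
        idx = np.argmax(np.abs(res), axis=1)
        es = res[np.arange(len(res)), idx]
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    es = np.where(denom[:, 0] == 0, np.nan, es)
    return es


def enrich(
    scores: pd.DataFrame,
    db: SignatureDB,
    n_perm: int = 1000,
    weight: float = 1.0,
    min_overlap: int = 2,
    seed: int | None = None,
    statistic: str = "area",
    fdr_scope: str = "category",
) -> pd.DataFrame:
    """Signature enrichment of signed site scores.

    Parameters
    ----------
    scores
        Single-treatment site scores (one row per site; run
        :func:`demultiplex` first). Must contain the site-key columns and
        ``score``.
    db
        Directional signature sets.
    n_perm
        Site-label permutations per signature (>= 100). Each permutation
        reassigns scores to sites while preserving the number of up- and
        down-direction members.
    weight
        Exponent on ``|score|`` in member increments.
    min_overlap
        Signatures with fewer measured member sites are excluded.
    statistic
        ``"area"`` (mean running sum; default) or ``"max"`` (classic
        maximum deviation).
    fdr_scope
        ``"category"`` adjusts BH within KINASE/PERT/PATH separately;
        ``"global"`` adjusts over all reported signatures.

    Returns a frame with ES, NES, permutation p, FDR, overlap and a status
    column; signatures whose permuted ES never matches the observed sign
    have NES/p reported missing with ``status="no_same_sign_perms"``.
    """
    if scores.empty:
        raise ValueError("scores table is empty")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if "treatment" in scores.columns and scores["treatment"].nunique() > 1:
        raise ValueError("enrich() expects scores for a single treatment")

    sids = np.array(
        [site_id(p, r, q) for p, r, q in zip(scores["protein"], scores["residue"], scores["position"])]
    )
    if len(set(sids)) != len(sids):
        raise ValueError("duplicate site ids in scores; demultiplex/collapse first")
    s = scores["score"].to_numpy(dtype=float)
    index = {sid: i for i, sid in enumerate(sids)}
    N = len(s)
    rng = np.random.default_rng(seed)

    rows = []
    for name, members in db.signatures.items():
        hits = [(index[sid], d) for sid, d in members if sid in index]
        m = len(hits)
        if m < min_overlap or m >= N:
            continue
        idx = np.array([i for i, _ in hits])
        down = np.array([d == "d" for _, d in hits])
        m_d = int(down.sum())

        adjusted = s.copy()
        adjusted[idx[down]] *= -1
        hit = np.zeros(N, dtype=bool)
        hit[idx] = True
        es = float(_running_es(adjusted[None, :], hit[None, :], weight, statistic)[0])

        # permutation null: random member subsets of the same size and
        # direction composition over the fixed score vector
        pick = np.argsort(rng.random((n_perm, N)), axis=1)[:, :m]
        A = np.tile(s, (n_perm, 1))
        H = np.zeros((n_perm, N), dtype=bool)
        rows_ix = np.arange(n_perm)[:, None]
        H[rows_ix, pick] = True
        if m_d:
            A[rows_ix, pick[:, :m_d]] *= -1
        es_perm = _running_es(A, H, weight, statistic)

        status = "ok"
        nes = p = np.nan
        if np.isnan(es):
            status = "degenerate"
        else:
            sgn = np.sign(es) if es != 0 else 1.0
            pool = es_perm[np.sign(es_perm) == sgn]
            if pool.size == 0:
                status = "no_same_sign_perms"
            else:
                nes = es / np.mean(np.abs(pool))
                p = float(np.mean(np.abs(pool) >= abs(es)))
        rows.append(
            {
                "signature": name,
                "category": db.categories.get(name, "KINASE"),
                "overlap": m,
                "es": es,
                "nes": nes,
                "pvalue": p,
                "status": status,
            }
        )

    out = pd.DataFrame(
        rows,
        columns=["signature", "category", "overlap", "es", "nes", "pvalue", "status"],
    )
    out["fdr"] = np.nan
    if not out.empty:
        groups = out.groupby("category").groups if fdr_scope == "category" else {"all": out.index}
        for _, ix in groups.items():
            sub = out.loc[ix]
            ok = sub["pvalue"].notna()
            if ok.any():
                out.loc[sub.index[ok], "fdr"] = multipletests(
                    sub.loc[ok, "pvalue"].to_numpy(), method="fdr_bh"
                )[1]
    out.attrs.update(
        statistic=statistic, n_perm=n_perm, weight=weight, fdr_scope=fdr_scope
    )
    return out
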