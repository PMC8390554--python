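"""Cross-dataset and cross-modality concordance statistics.

Kendall tau-b of per-gene enrichment odds ratios (optionally through a
homolog map), weighted Pearson correlation of per-gene fold changes
(weights -log10 p of the paired statistic), re-export of the gene direction
rule for hyper/hypo overlap sets, and the exacerbation odds test comparing
effect magnitudes of two contrasts over shared cytosines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import PanelAnnotation, ValidationError
from .enrichment import EnrichResult, fisher_or, gene_stats


def apply_homolog_map(
    values_a: pd.Series,
    values_b: pd.Series,
    homolog_map: pd.DataFrame | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Pair two per-gene series, optionally through a two-column homolog map
    (gene_id_a, gene_id_b).  Many-to-many maps must be reduced to one-to-one
    upstream; duplicated ids raise."""
    if homolog_map is None:
        shared = sorted(set(values_a.index) & set(values_b.index))
        return (values_a.loc[shared].to_numpy(dtype=float),
                values_b.loc[shared].to_numpy(dtype=float), shared)
    hm = homolog_map.reset_index(drop=True)
    if hm["gene_id_a"].duplicated().any() or hm["gene_id_b"].duplicated().any():
        raise ValidationError("homolog map is not one-to-one")
    hm = hm[hm["gene_id_a"].isin(values_a.index)
            & hm["gene_id_b"].isin(values_b.index)]
    return (values_a.loc[hm["gene_id_a"]].to_numpy(dtype=float),
            values_b.loc[hm["gene_id_b"]].to_numpy(dtype=float),
            hm["gene_id_a"].tolist())


def reduce_homolog_map(candidates: pd.DataFrame,
                       site_counts_a: pd.Series,
                       site_counts_b: pd.Series) -> pd.DataFrame:
    """Reduce a many-to-many homolog candidate table to one-to-one pairs,
    keeping for each conflict the pair with the highest combined site count."""
    cand = candidates.copy()
    cand["score"] = (cand["gene_id_a"].map(site_counts_a).fillna(0)
                     + cand["gene_id_b"].map(site_counts_b).fillna(0))
    cand = cand.sort_values(["score", "gene_id_a", "gene_id_b"],
                            ascending=[False, True, True], kind="stable")
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    rows = []
    for _, row in cand.iterrows():
        if row["gene_id_a"] in seen_a or row["gene_id_b"] in seen_b:
            continue
        seen_a.add(row["gene_id_a"])
        seen_b.add(row["gene_id_b"])
        rows.append(row[["gene_id_a", "gene_id_b"]])
    return pd.DataFrame(rows).reset_index(drop=True)


def kendall_concordance(
    gene_or_a: pd.Series,
    gene_or_b: pd.Series,
    homolog_map: pd.DataFrame | None = None,
) -> tuple[float, float, int]:
    """Tie-corrected Kendall tau-b of paired per-gene odds ratios.

    Two-sided p from the exact null distribution for n <= 8 without ties,
    otherwise the normal approximation.  Constant vectors yield (nan, nan).
    """
    x, y, genes = apply_homolog_map(gene_or_a, gene_or_b, homolog_map)
    good = np.isfinite(x) & np.isfinite(y)
    x, y = x[good], y[good]
    n = len(x)
    if n < 3:
        raise ValidationError("need at least 3 mapped gene pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan, n
    has_ties = (len(np.unique(x)) < n) or (len(np.unique(y)) < n)
    method = "exact" if (n <= 8 and not has_ties) else "asymptotic"
    res = stats.kendalltau(x, y, variant="b", method=method)
    return float(res.statistic), float(res.pvalue), n


def weighted_pearson(
    x: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[float, float]:
    """Weighted Pearson correlation with a t-approximation p-value.

    The effective sample size for the test is (sum w)^2 / sum(w^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (len(x) == len(y) == len(w)) or len(x) < 3:
        raise ValidationError("need equal-length vectors of length >= 3")
    if (w < 0).any():
        raise ValidationError("weights must be non-negative")
    sw = w.sum()
    if sw <= 0:
        raise ValidationError("total weight must be positive")
    mx = np.sum(w * x) / sw
    my = np.sum(w * y) / sw
    cov = np.sum(w * (x - mx) * (y - my)) / sw
    vx = np.sum(w * (x - mx) ** 2) / sw
    vy = np.sum(w * (y - my) ** 2) / sw
    if vx <= 0 or vy <= 0:
        return np.nan, np.nan
    r = float(cov / np.sqrt(vx * vy))
    n_eff = sw**2 / np.sum(w**2)
    df = n_eff - 2
    if df <= 0 or abs(r) >= 1:
        return r, np.nan if df <= 0 else 0.0
    t = r * np.sqrt(df / (1 - r**2))
    return r, float(2 * stats.t.sf(abs(t), df))


def gene_direction_summary(
    fits: pd.DataFrame,
    annotation: PanelAnnotation,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene signed disruption calls for cross-study overlap figures.

    A gene is disrupted when it has at least one significant cytosine; its
    direction follows the majority/tie-break rule of the gene statistics."""
    gs = gene_stats(fits, annotation, alpha=alpha)
    gs["disrupted"] = gs["n_sig"] > 0
    return gs[["gene_id", "disrupted", "direction", "wmfc", "n_sig"]]


def exacerbation_test(
    fits_a: pd.DataFrame,
    fits_b: pd.DataFrame,
    alpha: float = 0.05,
    significance: str = "a",
) -> EnrichResult:
    """Odds of greater absolute effect in dataset A among differentially
    methylated sites versus non-significant loci.

    ``significance`` selects which sites count as differentially methylated:
    ``"a"`` (significant in the A contrast; default), ``"union"`` or
    ``"intersection"`` of the two contrasts."""
    key = ["chrom", "pos", "strand", "context"]
    merged = fits_a.merge(fits_b, on=key, suffixes=("_a", "_b"))
    if merged.empty:
        raise ValidationError("fit tables share no cytosine keys")
    qa = merged["q_a"].to_numpy(dtype=float)
    qb = merged["q_b"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if significance == "a":
            sig = qa < alpha
        elif significance == "union":
            sig = (qa < alpha) | (qb < alpha)
        elif significance == "intersection":
            sig = (qa < alpha) & (qb < alpha)
        else:
            raise ValidationError(f"unknown significance rule {significance!r}")
    sig &= ~np.isnan(qa) & ~np.isnan(qb)
    scored = ~np.isnan(qa) & ~np.isnan(qb)
    greater = (np.abs(merged["pct_change_a"].to_numpy(dtype=float))
               > np.abs(merged["pct_change_b"].to_numpy(dtype=float)))
    a = int((greater & sig).sum())
    b = int((~greater & sig).sum())
    c = int((greater & ~sig & scored).sum())
    d = int((~greater & ~sig & scored).sum())
    return fisher_or((a, b, c, d), "two-sided", label="exacerbation")
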