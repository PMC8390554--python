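"""Robust rank aggregation of per-gene enrichment rankings across datasets.

Genes are ranked within each dataset by their one-sided gene-level enrichment
p-value, ranks are normalised to (0, 1], and each gene's rank vector is scored
by the beta order-statistic: for the j-th smallest normalised rank r_(j) of k
lists, the upper-tail probability that at least j of k independent Uniform(0,1)
variables fall at or below r_(j) is Beta(j, k-j+1).cdf(r_(j)); the score rho is
the minimum over j, and the Bonferroni-style adjusted score is min(1, rho*k).
Genes ranking consistently near the top across lists float to the top.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import ValidationError


def normalize_ranks(pvalues: pd.DataFrame, missing_rank: float = 1.0) -> pd.DataFrame:
    """Normalised ranks per dataset column.

    Ties get average ranks; ranks are divided by the number of ranked genes
    in the column; genes absent from a dataset receive ``missing_rank``
    (worst, 1.0, by default)."""
    if pvalues.shape[0] < 2:
        raise ValidationError("each dataset must rank at least 2 genes")
    out = {}
    for col in pvalues.columns:
        p = pvalues[col]
        n = int(p.notna().sum())
        if n < 2:
            raise ValidationError(f"dataset {col!r} ranks fewer than 2 genes")
        r = p.rank(method="average") / n
        out[col] = r.fillna(missing_rank)
    return pd.DataFrame(out, index=pvalues.index)


def rra_rho(r: np.ndarray, k: int | None = None) -> float:
    """Beta order-statistic score of an ascending normalised rank vector."""
    r = np.asarray(r, dtype=float)
    if np.any(np.diff(r) < 0):
        raise ValidationError("rank vector must be sorted ascending")
    if np.any((r <= 0) | (r > 1)):
        raise ValidationError("normalised ranks must lie in (0, 1]")
    k = len(r) if k is None else k
    if len(r) != k:
        raise ValidationError("rank vector length must equal k")
    j = np.arange(1, k + 1)
    tails = stats.beta.cdf(r, j, k - j + 1)
    return float(np.min(tails))


def aggregate(rank_matrix: pd.DataFrame) -> pd.DataFrame:
    """Score every gene; returns a table sorted ascending by adjusted score
    (ties broken by gene_id)."""
    k = rank_matrix.shape[1]
    rows = []
    for gene, row in rank_matrix.iterrows():
        r = np.sort(row.to_numpy(dtype=float))
        rho = rra_rho(r, k)
        rows.append({"gene_id": gene, "rho": rho,
                     "p_adj": min(1.0, rho * k)})
    out = pd.DataFrame(rows).sort_values(
        ["p_adj", "gene_id"], kind="stable").reset_index(drop=True)
    for col in rank_matrix.columns:
        out[f"rank_{col}"] = rank_matrix.loc[out["gene_id"], col].to_numpy()
    return out


def aggregate_gene_tables(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Aggregate gene-level enrichment tables (gene_id, p_one_sided) from
    two or more datasets into a consensus ranking."""
    if len(tables) < 1:
        raise ValidationError("need at least one gene table")
    pvals = pd.DataFrame({
        name: tab.set_index("gene_id")["p_one_sided"]
        for name, tab in tables.items()
    })
    ranks = normalize_ranks(pvals)
    return aggregate(ranks)
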