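"""Age-effect modelling and per-gene epigenetic aging rates.

The age model is the same robust differential engine with diagnosis, age and
a diagnosis-age interaction; group-specific age slopes are contrasts on the
age and interaction coefficients (control slope = age; case slope = age +
interaction).  The per-gene aging rate is the significance-weighted mean of
the gene's per-cytosine age slopes (weights -log10 p), forced to zero for
genes without a single cytosine passing FDR q < 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import BetaMatrix, Config, MethylCounts, PanelAnnotation, ValidationError
from .differential import run_differential
from .enrichment import geneset_overlap, fisher_or, EnrichResult


def fit_age_model(
    data: MethylCounts | BetaMatrix,
    sheet: pd.DataFrame,
    config: Config | None = None,
    covariates: tuple[str, ...] = ("group", "age", "sex", "pmi", "batch"),
    use_surrogates: bool = True,
) -> dict[str, pd.DataFrame]:
    """Group-specific age slopes per cytosine.

    Returns fit tables for contrasts ``age_control``, ``age_case`` and
    ``age_diff`` (the interaction, case slope minus control slope); the
    ``pct_change`` column is percentage points per year.
    """
    if "age" not in sheet.columns:
        raise ValidationError("sample sheet lacks an age column")
    if sheet["age"].nunique() < 2:
        raise ValidationError("age is constant; age effects are unidentifiable")
    contrasts = {
        "age_control": {"age": 1.0},
        "age_case": {"age": 1.0, "group:age": 1.0},
        "age_diff": {"group:age": 1.0},
    }
    return run_differential(
        data, sheet, config, covariates=covariates,
        interactions=(("group", "age"),), contrasts=contrasts,
        use_surrogates=use_surrogates,
    )


def gene_aging_rate(
    agefit: pd.DataFrame,
    annotation: PanelAnnotation,
    alpha: float = 0.05,
    weight_base: float = 10.0,
) -> pd.DataFrame:
    """Per-gene aging rate (percentage points per year, signed).

    rate = sum(w_i * slope_i) / sum(w_i) over all the gene's cytosines with
    w_i = -log10(p_i); genes with no cytosine at age-effect q < ``alpha``
    are zeroed (rate 0, ``zeroed`` True)."""
    assigned = annotation.assign_genes(agefit[["chrom", "pos"]])
    p = np.clip(agefit["p"].to_numpy(dtype=float), 1e-300, 1.0)
    w = -np.log(p) / np.log(weight_base)
    slope = agefit["pct_change"].to_numpy(dtype=float)
    q = agefit["q"].to_numpy(dtype=float)
    rows = []
    for gid in annotation.genes["gene_id"]:
        in_gene = (assigned == gid).to_numpy(dtype=bool)
        good = in_gene & np.isfinite(w) & np.isfinite(slope)
        if not good.any():
            continue
        with np.errstate(invalid="ignore"):
            any_sig = bool(np.any(q[in_gene] < alpha))
        if any_sig and np.sum(w[good]) > 0:
            rate = float(np.sum(w[good] * slope[good]) / np.sum(w[good]))
            zeroed = False
        else:
            rate, zeroed = 0.0, True
        rows.append({"gene_id": gid, "rate": rate, "zeroed": zeroed,
                     "n_sites": int(good.sum())})
    return pd.DataFrame(rows)


def age_pd_correlation(
    agefit: pd.DataFrame,
    pdfit: pd.DataFrame,
    alpha_nominal: float = 0.05,
) -> tuple[float, float, int] | None:
    """Pearson correlation of absolute age effects with absolute case-control
    effects over loci nominally significant (unadjusted p < 0.05) in both."""
    key = ["chrom", "pos", "strand", "context"]
    merged = agefit.merge(pdfit, on=key, suffixes=("_age", "_pd"))
    sel = (merged["p_age"] < alpha_nominal) & (merged["p_pd"] < alpha_nominal)
    sub = merged[sel]
    if len(sub) < 3:
        return None
    x = np.abs(sub["pct_change_age"].to_numpy(dtype=float))
    y = np.abs(sub["pct_change_pd"].to_numpy(dtype=float))
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(len(sub))


def compare_group_rates(
    rates_control: pd.DataFrame,
    rates_case: pd.DataFrame,
) -> dict:
    """Compare per-gene aging-rate tables between groups.

    Returns the overlap of non-zeroed (aging-affected) genes as a two-sided
    Fisher test over the shared gene universe, the direction-agreement Fisher
    test over jointly non-zeroed genes ({case sign} x {control sign}), and a
    paired t-test on absolute rates over jointly non-zeroed genes.
    """
    a = rates_control.set_index("gene_id")
    b = rates_case.set_index("gene_id")
    universe = set(a.index) & set(b.index)
    if not universe:
        raise ValidationError("rate tables share no genes")
    nz_a = {g for g in universe if not a.loc[g, "zeroed"]}
    nz_b = {g for g in universe if not b.loc[g, "zeroed"]}
    out: dict[str, object] = {"n_genes": len(universe),
                              "n_nonzero_control": len(nz_a),
                              "n_nonzero_case": len(nz_b)}
    try:
        out["overlap"] = geneset_overlap(nz_a, nz_b, universe, "nonzero_overlap")
    except ValidationError:
        out["overlap"] = None
    joint = sorted(nz_a & nz_b)
    out["n_joint"] = len(joint)
    if len(joint) < 2:
        out["direction_agreement"] = None
        out["paired_t_p"] = np.nan
        return out
    sa = np.sign(a.loc[joint, "rate"].to_numpy(dtype=float))
    sb = np.sign(b.loc[joint, "rate"].to_numpy(dtype=float))
    tbl = (int(np.sum((sb > 0) & (sa > 0))), int(np.sum((sb > 0) & (sa <= 0))),
           int(np.sum((sb <= 0) & (sa > 0))), int(np.sum((sb <= 0) & (sa <= 0))))
    try:
        out["direction_agreement"] = fisher_or(tbl, "two-sided",
                                               label="direction_agreement")
    except ValidationError:
        out["direction_agreement"] = None
    xa = np.abs(a.loc[joint, "rate"].to_numpy(dtype=float))
    xb = np.abs(b.loc[joint, "rate"].to_numpy(dtype=float))
    if np.allclose(xa, xb):
        out["paired_t_p"] = 1.0
    else:
        out["paired_t_p"] = float(stats.ttest_rel(xb, xa).pvalue)
    out["mean_abs_rate_control"] = float(np.mean(xa))
    out["mean_abs_rate_case"] = float(np.mean(xb))
    return out
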