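"""Fisher odds-ratio enrichment constructions on per-cytosine fit tables.

Every enrichment and overlap statistic is an odds ratio of a 2x2 table with
significance from Fisher's exact test: direction of change, genomic-element
membership, distance-to-TSS bins, pathway membership, per-gene enrichment
(the unit consumed by rank aggregation), gene-set overlaps, and top-site
element concordance across datasets.

Conventions: the sample odds ratio (a*d)/(b*c) with infinity when b*c = 0;
two-sided p by the point-probability rule; 95% CI by the Woolf log-OR normal
interval with a Haldane 0.5 correction when any cell is zero; the per-gene
test is one-sided (greater).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import PanelAnnotation, PATHWAYS, ValidationError


@dataclass
class EnrichResult:
    or_value: float
    p: float
    ci_low: float
    ci_high: float
    n_fg: int
    n_bg: int
    label: str = ""
    table: tuple[int, int, int, int] | None = None

    def as_dict(self) -> dict:
        return {
            "label": self.label, "or": self.or_value, "p": self.p,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "n_fg": self.n_fg, "n_bg": self.n_bg,
        }


def _sample_or(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return np.inf if a * d > 0 else np.nan
    return (a * d) / (b * c)


def _woolf_ci(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5  # Haldane correction
    log_or = np.log(cells[0] * cells[3] / (cells[1] * cells[2]))
    se = np.sqrt(np.sum(1.0 / cells))
    return float(np.exp(log_or - 1.959963984540054 * se)), \
        float(np.exp(log_or + 1.959963984540054 * se))


def fisher_or(
    table: tuple[int, int, int, int] | np.ndarray,
    alternative: str = "two-sided",
    label: str = "",
) -> EnrichResult:
    """Fisher's exact test on a 2x2 table (a, b, c, d) = [[a, b], [c, d]].

    ``a`` counts foreground-in, ``b`` foreground-out, ``c`` background-in,
    ``d`` background-out.  ``alternative`` is ``two-sided`` (point-probability
    rule) or ``greater`` (upper tail).
    """
    arr = np.asarray(table, dtype=np.int64).reshape(2, 2)
    if (arr < 0).any():
        raise ValidationError("negative cell count")
    if arr.sum() == 0:
        raise ValidationError("all-zero 2x2 table")
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    alt = {"two-sided": "two-sided", "two_sided": "two-sided",
           "greater": "greater"}[alternative]
    p = float(stats.fisher_exact(arr, alternative=alt).pvalue)
    lo, hi = _woolf_ci(a, b, c, d)
    return EnrichResult(_sample_or(a, b, c, d), p, lo, hi,
                        n_fg=a + b, n_bg=c + d, label=label,
                        table=(a, b, c, d))


def _significant(fits: pd.DataFrame, alpha: float, subset: str = "all") -> np.ndarray:
    q = fits["q"].to_numpy()
    with np.errstate(invalid="ignore"):
        sig = q < alpha
    sig &= ~np.isnan(q)
    if subset == "hyper":
        sig &= fits["direction"].to_numpy() > 0
    elif subset == "hypo":
        sig &= fits["direction"].to_numpy() < 0
    elif subset != "all":
        raise ValidationError(f"unknown direction subset {subset!r}")
    return sig


def directional_enrichment(fits: pd.DataFrame, alpha: float = 0.05) -> EnrichResult:
    """Odds of hypermethylation among significant cytosines versus the rest
    of the interrogated loci."""
    sig = _significant(fits, alpha)
    hyper = fits["direction"].to_numpy() > 0
    scored = fits["q"].notna().to_numpy()
    a = int((sig & hyper).sum())
    b = int((sig & ~hyper & scored).sum())
    c = int((~sig & hyper & scored).sum())
    d = int((~sig & ~hyper & scored).sum())
    if a + b == 0:
        return EnrichResult(np.nan, 1.0, np.nan, np.nan, 0, c + d,
                            label="hyper_vs_hypo")
    return fisher_or((a, b, c, d), "two-sided", label="hyper_vs_hypo")


def element_enrichment(
    fits: pd.DataFrame,
    annotation: PanelAnnotation,
    subset: str = "all",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per element class: significant (optionally direction-restricted)
    cytosines inside vs outside the element versus the rest of the sites."""
    sig = _significant(fits, alpha, subset)
    scored = fits["q"].notna().to_numpy()
    rows = []
    for cls in sorted(annotation.elements):
        inside = annotation.elements[cls].contains(
            fits["chrom"].to_numpy(), fits["pos"].to_numpy())
        a = int((sig & inside).sum())
        b = int((sig & ~inside).sum())
        c = int((~sig & scored & inside).sum())
        d = int((~sig & scored & ~inside).sum())
        if a + c == 0:  # element covers no panel sites
            rows.append({"label": cls, "or": np.nan, "p": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "n_fg": a + b, "n_bg": c + d})
            continue
        rows.append(fisher_or((a, b, c, d), "two-sided", label=cls).as_dict())
    return pd.DataFrame(rows)


def tss_bin_enrichment(
    fits: pd.DataFrame,
    annotation: PanelAnnotation,
    bin_bp: int = 20000,
    strata: dict[str, list[str]] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Enrichment per (distance bin, gene stratum).

    Each cytosine is assigned a half-open ``bin_bp``-wide bin of the unsigned
    distance to the nearest panel-gene TSS; per stratum (default: lysosome
    genes vs the rest) and bin, within-bin significant density is compared to
    the outside-bin density of the same stratum.
    """
    dist, nearest = annotation.nearest_tss_distance(fits[["chrom", "pos"]])
    bins = (dist // bin_bp).astype(int)
    if strata is None:
        lyso = set(annotation.pathway_genes("lysosome"))
        all_genes = set(annotation.genes["gene_id"])
        strata = {"lysosome": sorted(lyso), "other": sorted(all_genes - lyso)}
    sig = _significant(fits, alpha)
    scored = fits["q"].notna().to_numpy()
    rows = []
    for name, genes in strata.items():
        gset = set(genes)
        in_stratum = nearest.map(lambda g: g in gset).to_numpy(dtype=bool)
        for b in sorted(np.unique(bins[in_stratum])):
            in_bin = in_stratum & (bins == b)
            out_bin = in_stratum & (bins != b)
            a = int((sig & in_bin).sum())
            bb = int((~sig & scored & in_bin).sum())
            cc = int((sig & out_bin).sum())
            d = int((~sig & scored & out_bin).sum())
            row = {"stratum": name, "bin": int(b),
                   "bin_start_bp": int(b) * bin_bp,
                   "n_sites": int(in_bin.sum())}
            if (a + bb == 0) or (cc + d == 0):
                row |= {"or": np.nan, "p": np.nan, "ci_low": np.nan,
                        "ci_high": np.nan, "n_fg": a + bb, "n_bg": cc + d}
            else:
                # table [[sig_in, nonsig_in], [sig_out, nonsig_out]]
                res = fisher_or((a, bb, cc, d), "two-sided")
                row |= {k: v for k, v in res.as_dict().items() if k != "label"}
            rows.append(row)
    return pd.DataFrame(rows)


def pathway_enrichment(
    fits: pd.DataFrame,
    annotation: PanelAnnotation,
    subset: str = "all",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per pathway: odds of significant cytosines at pathway genes versus
    the rest of the interrogated sites."""
    assigned = annotation.assign_genes(fits[["chrom", "pos"]])
    sig = _significant(fits, alpha, subset)
    scored = fits["q"].notna().to_numpy()
    rows = []
    for pw in sorted(PATHWAYS):
        genes = set(annotation.pathway_genes(pw))
        if not genes:
            continue
        inside = assigned.map(lambda g: g in genes if pd.notna(g) else False)
        inside = inside.to_numpy(dtype=bool)
        a = int((sig & inside).sum())
        b = int((sig & ~inside).sum())
        c = int((~sig & scored & inside).sum())
        d = int((~sig & scored & ~inside).sum())
        if a + c == 0:
            continue
        res = fisher_or((a, b, c, d), "two-sided", label=pw)
        rows.append(res.as_dict() | {"n_genes": len(genes)})
    return pd.DataFrame(rows)


def gene_stats(
    fits: pd.DataFrame,
    annotation: PanelAnnotation,
    alpha: float = 0.05,
    weight_base: float = 10.0,
) -> pd.DataFrame:
    """Per-gene enrichment statistics.

    For each panel gene: the one-sided (greater) Fisher odds ratio of
    significant-site density within the gene versus the rest of the
    interrogated panel; the direction call by majority sign of the gene's
    significant cytosines, ties resolved by the sign of the weighted mean
    fold change over ALL the gene's cytosines (weights -log p); and that
    weighted mean percentage-point change (``wmfc``).
    """
    assigned = annotation.assign_genes(fits[["chrom", "pos"]])
    sig = _significant(fits, alpha)
    scored = fits["q"].notna().to_numpy()
    total_sig = int(sig.sum())
    total_scored = int(scored.sum())
    p_floor = np.clip(fits["p"].to_numpy(dtype=float), 1e-300, 1.0)
    weights = -np.log(p_floor) / np.log(weight_base)
    pct = fits["pct_change"].to_numpy(dtype=float)
    direction = fits["direction"].to_numpy()

    rows = []
    for gid in annotation.genes["gene_id"]:
        in_gene = (assigned == gid).to_numpy(dtype=bool)
        n_sites = int((in_gene & scored).sum())
        if n_sites == 0:
            continue
        sig_in = int((sig & in_gene).sum())
        nonsig_in = int((~sig & scored & in_gene).sum())
        sig_out = total_sig - sig_in
        nonsig_out = total_scored - total_sig - nonsig_in
        res = fisher_or((sig_in, nonsig_in, sig_out, nonsig_out), "greater",
                        label=gid)
        w = weights[in_gene & scored]
        x = pct[in_gene & scored]
        good = np.isfinite(w) & np.isfinite(x)
        wmfc = float(np.sum(w[good] * x[good]) / np.sum(w[good])) \
            if good.any() and np.sum(w[good]) > 0 else np.nan
        sig_dirs = direction[sig & in_gene]
        vote = int(np.sum(sig_dirs > 0)) - int(np.sum(sig_dirs < 0))
        if vote > 0:
            call = 1
        elif vote < 0:
            call = -1
        else:
            call = int(np.sign(wmfc)) if np.isfinite(wmfc) else 0
        rows.append({
            "gene_id": gid, "sig_in": sig_in, "nonsig_in": nonsig_in,
            "sig_out": sig_out, "nonsig_out": nonsig_out,
            "or": res.or_value, "p_one_sided": res.p,
            "direction": call, "wmfc": wmfc, "n_sig": sig_in,
        })
    return pd.DataFrame(rows)


def geneset_overlap(
    set_a: set[str],
    set_b: set[str],
    universe: set[str],
    label: str = "overlap",
) -> EnrichResult:
    """Two-sided Fisher test of membership association over a gene universe."""
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    if not set(set_a) <= universe or not set(set_b) <= universe:
        raise ValidationError("sets must be subsets of the universe")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - len(set_a | set_b)
    return fisher_or((a, b, c, d), "two-sided", label=label)


def top_sites_element_concordance(
    fits_a: pd.DataFrame,
    fits_b: pd.DataFrame,
    annotation: PanelAnnotation,
    k: int = 5000,
    match_bp: int = 0,
) -> pd.DataFrame:
    """Concordance of top-k most significant sites at the element level.

    For each element class, each element instance is tested for containing a
    top-k site of each dataset (instances matched by interval identity,
    optionally expanded by ``match_bp`` on both flanks for cross-tissue
    enhancer/promoter matching); the 2x2 over instances {top in A} x
    {top in B} yields the concordance odds ratio.
    """
    import warnings

    def top_mask(fits):
        p = fits["p"].to_numpy(dtype=float)
        order = np.argsort(np.where(np.isnan(p), np.inf, p), kind="stable")
        kk = min(k, int(np.sum(~np.isnan(p))))
        mask = np.zeros(len(p), dtype=bool)
        mask[order[:kk]] = True
        return mask

    if k > min(fits_a["p"].notna().sum(), fits_b["p"].notna().sum()):
        warnings.warn("k exceeds the number of scored sites; clamped",
                      stacklevel=2)
    ta, tb = top_mask(fits_a), top_mask(fits_b)
    rows = []
    for cls in sorted(annotation.elements):
        iv = annotation.elements[cls].intervals
        has_a = np.zeros(len(iv), dtype=bool)
        has_b = np.zeros(len(iv), dtype=bool)
        for which, (fits, mask, out) in enumerate(
                [(fits_a, ta, has_a), (fits_b, tb, has_b)]):
            chrom = fits["chrom"].to_numpy()[mask]
            pos = fits["pos"].to_numpy()[mask]
            for i, (c_, s_, e_) in enumerate(
                    zip(iv["chrom"], iv["start"], iv["end"])):
                s_, e_ = s_ - match_bp, e_ + match_bp
                out[i] = bool(np.any((chrom == c_) & (pos > s_) & (pos <= e_)))
        a = int((has_a & has_b).sum())
        b = int((has_a & ~has_b).sum())
        c = int((~has_a & has_b).sum())
        d = int((~has_a & ~has_b).sum())
        row = {"label": cls, "n_instances": len(iv)}
        if a + b + c + d == 0:
            row |= {"or": np.nan, "p": np.nan, "ci_low": np.nan,
                    "ci_high": np.nan, "n_fg": 0, "n_bg": 0}
        else:
            row |= {kk: v for kk, v in
                    fisher_or((a, b, c, d), "two-sided").as_dict().items()
                    if kk != "label"}
        rows.append(row)
    return pd.DataFrame(rows)
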