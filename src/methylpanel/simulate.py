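"""Synthetic padlock-panel methylation data with known ground truth.

The generator emulates the structure of a targeted bisulfite panel: a set of
genes, each with probe regions spanning a +/- window around its TSS, cytosine
read counts drawn beta-binomially over negative-binomial coverage, case/control
mean-shift effects with a directional (hyper/hypo) bias, linear age effects,
batch offsets, latent-factor (cell-mixture-like) structure, technical
replicates, and occasional globally shifted outlier samples.

Effects are specified in percentage points of methylation.  A planted shift of
``t`` percentage points at baseline ``b`` is realised on the logit scale as
``logit(b) + [logit(clamp(b + t/100)) - logit(b)]`` — the logit-scale
equivalent of the stated percentage-point shift — whose logistic
back-transform is exactly ``clamp(b + t/100)``.  Planted effects are therefore
directly comparable to the pipeline's percentage-point output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import MethylCounts, PanelAnnotation, ValidationError

_EPS = 1e-3  # clamp bound for cell means

# fixed child-stream order; appending streams never perturbs earlier stages
_STREAMS = (
    "panel", "baseline", "effects", "age", "batch", "latent",
    "coverage", "counts", "replicates", "outliers", "samples",
)


@dataclass
class SimConfig:
    """Study conditions of the synthetic panel.

    Defaults mirror a deeply sequenced targeted panel: ~100 genes, coverage
    around 100x, 20 cases vs 20 controls aged 40-90, a 10-percentage-point
    case effect at 10% of genes with a hypermethylation bias of 0.7, and mild
    beta-binomial overdispersion.
    """

    n_genes: int = 100
    cytosines_per_gene: tuple[int, int] = (5, 30)
    window_bp: int = 10000
    n_case: int = 20
    n_control: int = 20
    coverage_mean: float = 100.0
    coverage_dispersion: float = 5.0
    baseline_beta_a: float = 2.0
    baseline_beta_b: float = 2.0
    frac_affected_genes: float = 0.1
    frac_affected_cytosines: float = 0.5
    effect_pct: float = 10.0
    hyper_fraction: float = 0.7
    age_range: tuple[float, float] = (40.0, 90.0)
    frac_age_cytosines: float = 0.0
    age_slope_pct_per_year: float = 0.4
    n_batches: int = 1
    batch_sd: float = 0.0
    batch_confounding: float = 0.0  # group-batch composition tilt in [0, 1)
    n_latent_factors: int = 0
    latent_sd: float = 0.0
    n_replicate_pairs: int = 0
    n_outlier_samples: int = 0
    outlier_shift_sd: float = 6.0
    rho: float = 0.01
    seed: int = 0
    panel_seed: int | None = None  # share a panel layout across datasets
    affected_pathway: str | None = None
    affected_element: str | None = None

    def __post_init__(self) -> None:
        for name in ("frac_affected_genes", "frac_affected_cytosines",
                     "hyper_fraction", "frac_age_cytosines"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.coverage_mean <= 0:
            raise ValidationError("coverage_mean must be positive")
        if not 0 <= self.rho < 1:
            raise ValidationError("rho must lie in [0, 1)")
        if self.cytosines_per_gene[0] < 1:
            raise ValidationError("cytosines_per_gene must be >= 1")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SimTruth:
    """Planted parameters: per-cytosine effects plus per-sample structure."""

    sites: pd.DataFrame  # gene_id, delta (pct), gamma (pct/year)
    batch_offsets: np.ndarray | None  # sites x batches, pct
    latent_loadings: np.ndarray | None  # sites x factors, pct
    latent_scores: np.ndarray | None  # samples x factors
    outlier_samples: list[str] = field(default_factory=list)
    clamped_fraction: float = 0.0
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return self.sites.copy()


def _streams(seed: int, panel_seed: int | None = None) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    rngs = {name: np.random.default_rng(ss)
            for name, ss in zip(_STREAMS, children)}
    if panel_seed is not None:
        # same gene/cytosine layout across datasets of one synthetic study
        rngs["panel"] = np.random.default_rng(
            np.random.SeedSequence(panel_seed).spawn(1)[0])
    return rngs


def _make_panel(cfg: SimConfig, rng: np.random.Generator):
    """Lay genes along chr1 with promoter/1to5kb/exon/intergenic elements."""
    spacing = max(4 * cfg.window_bp, 100_000)
    gene_rows, elem_rows, key_rows = [], [], []
    pathways = sorted({"autophagy", "CMA", "lysosome", "macroautophagy",
                       "selective_autophagy"})
    n_per_gene = rng.integers(cfg.cytosines_per_gene[0],
                              cfg.cytosines_per_gene[1] + 1, size=cfg.n_genes)
    for g in range(cfg.n_genes):
        gid = f"G{g:04d}"
        tss = spacing // 2 + g * spacing
        pw = pathways[g % len(pathways)] if rng.random() < 0.8 else ""
        gene_rows.append((gid, "chr1", tss, "+", cfg.window_bp, pw,
                          bool(rng.random() < 0.05)))
        # promoter [tss-2000, tss+500), upstream 1to5kb, three exons
        elem_rows.append(("chr1", max(tss - 2001, 0), tss + 500, "promoter"))
        elem_rows.append(("chr1", max(tss - 5001, 0), tss - 2001, "1to5kb"))
        for e in range(3):
            s = tss + 1000 + 2000 * e
            elem_rows.append(("chr1", s, s + 400, "exon"))
        elem_rows.append(("chr1", tss + cfg.window_bp, tss + spacing // 2,
                          "intergenic"))
        lo, hi = tss - cfg.window_bp, tss + cfg.window_bp
        pos = np.sort(rng.choice(np.arange(max(lo, 1), hi + 1),
                                 size=n_per_gene[g], replace=False))
        for p in pos:
            key_rows.append(("chr1", int(p), "+", "CpG", gid))
    genes = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "chrom", "tss", "strand", "window_bp",
                 "pathways", "gwas_flag"],
    )
    elements = pd.DataFrame(elem_rows, columns=["chrom", "start", "end", "name"])
    keys = pd.DataFrame(key_rows,
                        columns=["chrom", "pos", "strand", "context", "gene_id"])
    return genes, elements, keys


def simulate_panel(cfg: SimConfig):
    """Simulate a panel dataset.

    Returns ``(counts, sheet, annotation, truth)``.  Fully reproducible from
    ``cfg.seed``; independent RNG streams per stage, so enabling one feature
    never perturbs the draws of another.
    """
    rng = _streams(cfg.seed, cfg.panel_seed)
    genes, elem_df, keys = _make_panel(cfg, rng["panel"])

    from .types import IntervalSet  # local import to avoid cycle at module load

    elements = {
        str(cls): IntervalSet(sub[["chrom", "start", "end"]])
        for cls, sub in elem_df.groupby("name", sort=True)
    }
    annotation = PanelAnnotation(genes=genes, elements=elements, snp_mask=None)

    n_sites = len(keys)
    n = cfg.n_case + cfg.n_control
    sample_ids = [f"S{j:03d}" for j in range(n)]
    group = np.array(["case"] * cfg.n_case + ["control"] * cfg.n_control)
    age = rng["samples"].uniform(*cfg.age_range, size=n)
    sex = rng["samples"].choice(["M", "F"], size=n)
    pmi = rng["samples"].uniform(2.0, 30.0, size=n)
    # optional group-batch confounding: cases tilt toward the later batches
    # (omitting a confounded batch then biases the group coefficient, which
    # is what surrogate adjustment must repair)
    if cfg.n_batches > 1 and cfg.batch_confounding > 0:
        grad = 2 * np.arange(cfg.n_batches) / (cfg.n_batches - 1) - 1
        batch = np.empty(n, dtype=int)
        for j in range(n):
            s = 1.0 if group[j] == "case" else -1.0
            w = np.clip(1.0 + cfg.batch_confounding * s * grad, 0, None)
            batch[j] = rng["batch"].choice(cfg.n_batches, p=w / w.sum())
    else:
        batch = rng["batch"].integers(0, cfg.n_batches, size=n)

    baseline = rng["baseline"].beta(cfg.baseline_beta_a, cfg.baseline_beta_b,
                                    size=n_sites)
    baseline = np.clip(baseline, 0.02, 0.98)

    # plant case effects: choose affected genes (optionally within a pathway),
    # then a fraction of each gene's cytosines; sign is constant within a gene
    delta = np.zeros(n_sites)
    gene_ids = genes["gene_id"].to_numpy()
    if cfg.affected_pathway:
        eligible = genes["pathways"].map(
            lambda ps: cfg.affected_pathway in ps).to_numpy()
    else:
        eligible = np.ones(len(genes), dtype=bool)
    n_aff = int(round(cfg.frac_affected_genes * len(genes)))
    n_aff = min(n_aff, int(eligible.sum()))
    affected_genes = rng["effects"].choice(gene_ids[eligible], size=n_aff,
                                           replace=False)
    site_gene = keys["gene_id"].to_numpy()
    in_element = None
    if cfg.affected_element:
        in_element = annotation.elements[cfg.affected_element].contains(
            keys["chrom"].to_numpy(), keys["pos"].to_numpy())
    for gid in affected_genes:
        sign = 1.0 if rng["effects"].random() < cfg.hyper_fraction else -1.0
        idx = np.flatnonzero(site_gene == gid)
        if in_element is not None:
            idx = idx[in_element[idx]]
        # plant only where the baseline can absorb the full shift, so the
        # truth table equals the realised simulation (no clamped effects)
        shifted = baseline[idx] + sign * cfg.effect_pct / 100.0
        idx = idx[(shifted >= 0.02) & (shifted <= 0.98)]
        if len(idx) == 0:
            continue
        k = max(1, int(round(cfg.frac_affected_cytosines * len(idx))))
        chosen = rng["effects"].choice(idx, size=k, replace=False)
        delta[chosen] = sign * cfg.effect_pct

    gamma = np.zeros(n_sites)
    n_age = int(round(cfg.frac_age_cytosines * n_sites))
    if n_age:
        idx = rng["age"].choice(n_sites, size=n_age, replace=False)
        sign = rng["age"].choice([-1.0, 1.0], size=n_age)
        gamma[idx] = sign * cfg.age_slope_pct_per_year

    batch_offsets = None
    if cfg.n_batches > 1 and cfg.batch_sd > 0:
        batch_offsets = rng["batch"].normal(0.0, cfg.batch_sd,
                                            size=(n_sites, cfg.n_batches))
    loadings = scores = None
    if cfg.n_latent_factors > 0 and cfg.latent_sd > 0:
        loadings = rng["latent"].normal(0.0, cfg.latent_sd,
                                        size=(n_sites, cfg.n_latent_factors))
        scores = rng["latent"].normal(0.0, 1.0, size=(n, cfg.n_latent_factors))

    # total percentage-point shift per cell, applied at each site's baseline
    age_c = age - np.mean(cfg.age_range)
    shift = (delta[:, None] * (group == "case")[None, :]
             + gamma[:, None] * age_c[None, :])
    if batch_offsets is not None:
        shift = shift + batch_offsets[:, batch]
    if loadings is not None:
        shift = shift + loadings @ scores.T

    mu = baseline[:, None] + shift / 100.0
    clamped = float(np.mean((mu < _EPS) | (mu > 1 - _EPS)))
    mu = np.clip(mu, _EPS, 1 - _EPS)

    # outliers: globally shift the last samples' means by >= outlier_shift_sd
    # SDs of the per-sample mean methylation (floored for degenerate designs)
    outliers: list[str] = []
    if cfg.n_outlier_samples > 0:
        sample_means = mu.mean(axis=0)
        sd = max(float(np.std(sample_means, ddof=1)), 0.005)
        picks = list(range(n - cfg.n_outlier_samples, n))
        for j in picks:
            direction = 1.0 if rng["outliers"].random() < 0.5 else -1.0
            mu[:, j] = np.clip(mu[:, j] + direction * cfg.outlier_shift_sd * sd,
                               _EPS, 1 - _EPS)
            outliers.append(sample_ids[j])

    def draw_counts(mu_mat, rng_counts):
        k = cfg.coverage_dispersion
        lam = rng_counts.gamma(k, cfg.coverage_mean / k, size=mu_mat.shape)
        N = rng_counts.poisson(lam)
        if cfg.rho > 0:
            a = mu_mat * (1 - cfg.rho) / cfg.rho
            b = (1 - mu_mat) * (1 - cfg.rho) / cfg.rho
            p = rng_counts.beta(a, b)
        else:
            p = mu_mat
        M = rng_counts.binomial(N, p)
        return M.astype(float), (N - M).astype(float), N == 0

    M, U, zero = draw_counts(mu, rng["counts"])
    M[zero] = np.nan
    U[zero] = np.nan

    # technical replicates: duplicate the first pairs with fresh count draws
    rep_group = [""] * n
    if cfg.n_replicate_pairs > 0:
        k = min(cfg.n_replicate_pairs, n)
        Mr, Ur, zr = draw_counts(mu[:, :k], rng["replicates"])
        Mr[zr] = np.nan
        Ur[zr] = np.nan
        M = np.hstack([M, Mr])
        U = np.hstack([U, Ur])
        rep_ids = [f"{sample_ids[j]}r" for j in range(k)]
        for j in range(k):
            rep_group[j] = f"R{j:03d}"
        rep_group += [f"R{j:03d}" for j in range(k)]
        rows = pd.DataFrame({
            "sample_id": rep_ids, "group": group[:k], "age": age[:k],
            "sex": sex[:k], "pmi": pmi[:k], "batch": batch[:k],
        })
    else:
        rows = None

    sheet = pd.DataFrame({
        "sample_id": sample_ids, "group": group, "age": age, "sex": sex,
        "pmi": pmi, "batch": batch,
    })
    if rows is not None:
        sheet = pd.concat([sheet, rows], ignore_index=True)
    sheet["replicate_group"] = rep_group
    all_ids = sheet["sample_id"].tolist()

    counts = MethylCounts(keys[["chrom", "pos", "strand", "context"]],
                          all_ids, M, U)
    truth = SimTruth(
        sites=pd.DataFrame({
            "chrom": keys["chrom"], "pos": keys["pos"],
            "strand": keys["strand"], "context": keys["context"],
            "gene_id": site_gene, "delta": delta, "gamma": gamma,
        }),
        batch_offsets=batch_offsets,
        latent_loadings=loadings,
        latent_scores=scores,
        outlier_samples=outliers,
        clamped_fraction=clamped,
        seed=cfg.seed,
    )
    if clamped > 0.01:
        import warnings

        warnings.warn(
            f"{clamped:.1%} of cell means clamped to [{_EPS}, {1 - _EPS}]; "
            "the configuration plants effects inconsistent with its baselines",
            stacklevel=2,
        )
    return counts, sheet, annotation, truth


def simulate_null(cfg: SimConfig):
    """simulate_panel with all planted case and age effects switched off."""
    return simulate_panel(cfg.replace(frac_affected_genes=0.0,
                                      frac_age_cytosines=0.0))
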