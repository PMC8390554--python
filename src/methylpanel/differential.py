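"""Per-cytosine robust differential-methylation modelling.

Beta values are shrunk towards the centre, B' = (B*(f-1) + 0.5)/f, and mapped
to m-values m = log2(B'/(1-B')).  Each cytosine is fitted by robust linear
regression (iteratively reweighted least squares with the Huber psi,
c = 1.345, MAD residual scale) against diagnosis, age, sex, postmortem
interval, batch and surrogate variables; moderated t-statistics are obtained
by empirical-Bayes shrinkage of the residual variances; p-values are adjusted
by Benjamini-Hochberg; effect sizes are reported both in m-units and as
percentage points of methylation obtained by back-transforming the fitted
m-values to the beta scale and refitting the same design.

Surrogate variables follow the residual-PCA rule: principal components of the
m-value residuals after regressing out the known covariates, keeping every
component explaining more than the configured share of variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .types import BetaMatrix, Config, MethylCounts, ValidationError

HUBER_C = 1.345
MAD_CONST = 1.4826


def beta_to_m(B: np.ndarray, f: float = 1000.0) -> np.ndarray:
    """Shrunk logit transform: B' = (B*(f-1)+0.5)/f, m = log2(B'/(1-B'))."""
    if f < 2:
        raise ValidationError("shrink factor f must be >= 2")
    B = np.asarray(B, dtype=float)
    Bp = (B * (f - 1.0) + 0.5) / f
    return np.log2(Bp / (1.0 - Bp))


def m_to_beta(m: np.ndarray) -> np.ndarray:
    """Inverse logit on the shrunk scale: B = 2^m / (2^m + 1)."""
    m = np.asarray(m, dtype=float)
    return special.expit(m * np.log(2.0))


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (NaNs propagate)."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# design matrices and contrasts


def design_matrix(
    sheet: pd.DataFrame,
    covariates: tuple[str, ...] = ("group", "age", "sex", "pmi", "batch"),
    interactions: tuple[tuple[str, str], ...] = (),
    extra: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build a full-rank design matrix from sample-sheet columns.

    Categorical columns (group, sex, batch) are dummy-coded against a
    reference level; constant columns are dropped (aliased with the
    intercept).  ``group`` codes case = 1, control = 0 so positive
    coefficients mean hypermethylation in cases.
    """
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(sheet))}
    for c in covariates:
        if c not in sheet.columns:
            continue
        v = sheet[c]
        if c == "group":
            cols["group"] = (v == "case").to_numpy(dtype=float)
        elif v.dtype.kind in "OUSb":
            levels = sorted(pd.unique(v.astype(str)))
            for lv in levels[1:]:
                cols[f"{c}[{lv}]"] = (v.astype(str) == lv).to_numpy(dtype=float)
        else:
            cols[c] = v.to_numpy(dtype=float)
    for a, b in interactions:
        if a in cols and b in cols:
            cols[f"{a}:{b}"] = cols[a] * cols[b]
    X = pd.DataFrame(cols, index=sheet.index)
    keep = ["Intercept"] + [c for c in X.columns[1:] if X[c].nunique() > 1]
    X = X[keep]
    if extra is not None:
        X = pd.concat([X, extra.set_axis(X.index)], axis=1)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        # drop aliased columns greedily (rightmost dependents go first)
        keep_idx: list[int] = []
        A = X.to_numpy()
        for j in range(X.shape[1]):
            trial = keep_idx + [j]
            if np.linalg.matrix_rank(A[:, trial]) == len(trial):
                keep_idx.append(j)
        X = X.iloc[:, keep_idx]
    return X


def contrast_vector(design: pd.DataFrame, spec: str | dict[str, float]) -> np.ndarray:
    """A contrast as a linear combination of design coefficients.

    ``spec`` is either a single column name or a {column: weight} mapping."""
    c = np.zeros(design.shape[1])
    if isinstance(spec, str):
        spec = {spec: 1.0}
    for name, w in spec.items():
        if name not in design.columns:
            raise ValidationError(f"contrast names unknown column {name!r}")
        c[design.columns.get_loc(name)] = w
    return c


# ---------------------------------------------------------------------------
# surrogate variables


@dataclass
class SurrogateSet:
    scores: np.ndarray  # samples x k, orthogonal columns
    k: int
    variance_explained: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores,
                            columns=[f"SV{i + 1}" for i in range(self.k)])


def estimate_surrogates(
    m: np.ndarray,
    design: pd.DataFrame,
    sv_var_threshold: float = 0.05,
) -> SurrogateSet:
    """Residual-PCA surrogate variables.

    Each cytosine's m-values are regressed on the known covariates (ordinary
    least squares, missing cells mean-imputed for this step only); the number
    of surrogate components is the count of residual principal components
    explaining more than ``sv_var_threshold`` of the variance, and the
    surrogate columns are those components' sample scores.
    """
    X = design.to_numpy()
    n, p = X.shape
    if n < p + 2:
        raise ValidationError("need at least 2 more samples than covariates")
    Y = np.asarray(m, dtype=float)
    obs = ~np.isnan(Y)
    row_mean = np.where(obs.any(axis=1),
                        np.nanmean(np.where(obs, Y, np.nan), axis=1), 0.0)
    Yf = np.where(obs, Y, row_mean[:, None])
    beta, *_ = np.linalg.lstsq(X, Yf.T, rcond=None)
    R = Yf - (X @ beta).T  # sites x samples
    R = R - R.mean(axis=1, keepdims=True)
    U_, S, Vt = np.linalg.svd(R.T, full_matrices=False)
    total = float(np.sum(S**2))
    if total == 0:
        return SurrogateSet(np.empty((n, 0)), 0, np.empty(0))
    share = S**2 / total
    k = int(np.sum(share > sv_var_threshold))
    # keep residual degrees of freedom: never let surrogates saturate the
    # design (small cohorts put every noise PC above the share threshold)
    k = min(k, max(0, n - p - 4))
    if k == 0:
        return SurrogateSet(np.empty((n, 0)), 0, share[:0])
    # residual PCA fixes the component count and the site-space directions;
    # the sample scores are then re-estimated by projecting the original
    # (per-site centred) m matrix onto those directions.  Residual scores
    # are orthogonal to every modelled covariate by construction, so they
    # could never carry the covariate-correlated share of a confounder;
    # the projection restores it, which is what adjustment needs.
    Yc = Yf - Yf.mean(axis=1, keepdims=True)
    scores = Yc.T @ Vt[:k].T  # samples x k
    # orthonormalise for numerical stability (order preserved)
    q, _ = np.linalg.qr(scores)
    scale = np.linalg.norm(scores, axis=0)
    return SurrogateSet(q * scale, k, share[:k])


# ---------------------------------------------------------------------------
# robust fitting


@dataclass
class RobustFit:
    """Raw per-cytosine robust regression results."""

    design: pd.DataFrame
    coef: np.ndarray  # sites x p
    sigma: np.ndarray  # robust residual SD (MAD-based at convergence)
    df_resid: np.ndarray
    cov_unscaled: np.ndarray  # sites x p x p, (X'X)^-1 on observed rows
    fitted: np.ndarray  # sites x samples (NaN at missing)
    ok: np.ndarray  # sites fitted successfully
    iterations: int = 0
    skipped: list[int] = field(default_factory=list)


def fit_robust(
    m: np.ndarray,
    design: pd.DataFrame,
    max_iter: int = 100,
    tol: float = 1e-6,
    c: float = HUBER_C,
) -> RobustFit:
    """Huber M-estimation by IRLS, vectorised across cytosines.

    Scale is re-estimated each iteration as 1.4826 x MAD of the residuals;
    convergence when the largest coefficient change is below ``tol``.
    Cytosines whose observed design is rank-deficient (or has fewer than
    rank + 2 complete cases) are skipped and logged in ``skipped``.
    """
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    Y = np.asarray(m, dtype=float)
    G = Y.shape[0]
    obs = ~np.isnan(Y)
    Y0 = np.where(obs, Y, 0.0)
    n_obs = obs.sum(axis=1)

    ok = n_obs >= p + 2
    # rank check on each distinct missingness pattern
    patterns, inverse = np.unique(obs, axis=0, return_inverse=True)
    for k, pat in enumerate(patterns):
        if pat.sum() >= p + 2 and np.linalg.matrix_rank(X[pat]) < p:
            ok[inverse == k] = False
    skipped = np.flatnonzero(~ok).tolist()

    w = obs.astype(float)
    coef = np.zeros((G, p))
    active = ok.copy()
    iterations = 0

    if ok.any():
        A = np.einsum("gn,np,nq->gpq", w[ok], X, X)
        b = np.einsum("gn,np->gp", w[ok] * Y0[ok], X)
        coef[ok] = np.linalg.solve(A, b[..., None])[..., 0]
    while active.any() and iterations < max_iter:
        iterations += 1
        resid = Y0[active] - coef[active] @ X.T
        resid_nan = np.where(obs[active], resid, np.nan)
        med = np.nanmedian(resid_nan, axis=1, keepdims=True)
        scale = MAD_CONST * np.nanmedian(np.abs(resid_nan - med), axis=1)
        scale = np.maximum(scale, 1e-10)
        u = np.abs(resid) / scale[:, None]
        hub = np.minimum(1.0, c / np.maximum(u, 1e-12))
        w_act = hub * obs[active]
        A = np.einsum("gn,np,nq->gpq", w_act, X, X)
        b = np.einsum("gn,np->gp", w_act * Y0[active], X)
        new = np.linalg.solve(A, b[..., None])[..., 0]
        delta = np.max(np.abs(new - coef[active]), axis=1)
        coef[active] = new
        still = delta >= tol
        idx = np.flatnonzero(active)
        active[idx[~still]] = False

    fitted = np.where(obs, coef @ X.T, np.nan)
    resid = np.where(obs, Y0 - coef @ X.T, np.nan)
    med = np.nanmedian(resid, axis=1, keepdims=True)
    scale = MAD_CONST * np.nanmedian(np.abs(resid - med), axis=1)
    scale = np.maximum(scale, 1e-10)
    df = np.maximum(n_obs - p, 0).astype(float)

    # residual SD by the Huber proposal with the Street-Carroll-Ruppert
    # correction (the convention of MASS summary.rlm): consistent at the
    # normal and accounting for the efficiency cost of downweighting
    u = np.where(obs, resid, np.nan) / scale[:, None]
    psi = np.clip(u, -c, c)
    dpsi = (np.abs(u) <= c).astype(float)
    dpsi[~obs] = np.nan
    m1 = np.nanmean(dpsi, axis=1)
    m2 = np.nanmean(dpsi**2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa = 1.0 + p * (m2 - m1**2) / (n_obs * m1**2)
        sigma = (scale * kappa / m1) * np.sqrt(
            np.nansum(psi**2, axis=1) / np.where(df > 0, df, np.nan))
    sigma = np.where(df > 0, sigma, np.nan)

    # unscaled coefficient covariance from the observed rows of the design
    cov = np.full((G, p, p), np.nan)
    for k, pat in enumerate(patterns):
        rows = inverse == k
        if not (ok & rows).any():
            continue
        Xk = X[pat]
        if Xk.shape[0] >= p and np.linalg.matrix_rank(Xk) == p:
            cov_k = np.linalg.inv(Xk.T @ Xk)
            cov[ok & rows] = cov_k
    sigma[~ok] = np.nan
    return RobustFit(design, coef, sigma, df, cov, fitted, ok, iterations,
                     skipped)


# ---------------------------------------------------------------------------
# empirical-Bayes moderation


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) / x < 1e-8:
            break
    return float(x)


D0_CAP = 1e7


def estimate_prior_variance(sigma2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to the sample variances.

    Returns the prior degrees of freedom d0 (capped at 1e7 for degenerate,
    near-identical variance sets) and the prior variance s0^2.  The fit works
    on log variances with digamma/trigamma corrections.
    """
    ok = np.isfinite(sigma2) & (sigma2 > 0) & (df > 0)
    s2 = sigma2[ok]
    d = df[ok]
    if s2.size < 2:
        raise ValidationError("need >= 2 positive residual variances")
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, d / 2.0)))
    if evar > 1.0 / D0_CAP:
        d0 = 2.0 * _trigamma_inverse(evar)
        d0 = min(d0, D0_CAP)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # (near-)identical variances: infinite-df prior, target their mean
        d0 = D0_CAP
        s02 = float(np.mean(s2))
    return d0, s02


def moderate_ebayes(
    effect: np.ndarray,
    se_unscaled: np.ndarray,
    sigma: np.ndarray,
    df: np.ndarray,
    d0: float | None = None,
    s02: float | None = None,
) -> pd.DataFrame:
    """Moderated t-statistics with empirical-Bayes variance shrinkage.

    Posterior variance s~^2 = (d0*s0^2 + df*s^2) / (d0 + df); the moderated t
    is effect / (s~ * unscaled SE) on df + d0 degrees of freedom, two-sided.
    """
    sigma2 = np.asarray(sigma, dtype=float) ** 2
    df = np.asarray(df, dtype=float)
    if d0 is None or s02 is None:
        d0, s02 = estimate_prior_variance(sigma2, df)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2_post = (d0 * s02 + df * sigma2) / (d0 + df)
        t = effect / (np.sqrt(s2_post) * se_unscaled)
        df_total = np.minimum(df + d0, 1e9)
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame({
        "t": t, "p": p, "s2_post": s2_post, "df_total": df_total,
    }).assign(d0=d0, s02=s02)


# ---------------------------------------------------------------------------
# percentage-point effect sizes


def percent_change(fit: RobustFit, contrast: np.ndarray) -> np.ndarray:
    """Effect size in percentage points of methylation.

    The fitted m-values are back-transformed to beta values and the same
    linear design is refitted (ordinary least squares over observed cells);
    the contrast coefficient x 100 is the percentage-point change per unit
    covariate.
    """
    X = fit.design.to_numpy(dtype=float)
    Bfit = m_to_beta(fit.fitted)
    obs = ~np.isnan(Bfit)
    B0 = np.where(obs, Bfit, 0.0)
    w = obs.astype(float)
    A = np.einsum("gn,np,nq->gpq", w, X, X)
    b = np.einsum("gn,np->gp", w * B0, X)
    out = np.full(Bfit.shape[0], np.nan)
    ok = fit.ok
    if ok.any():
        coefB = np.linalg.solve(A[ok], b[ok][..., None])[..., 0]
        out[ok] = 100.0 * coefB @ contrast
    return out


# ---------------------------------------------------------------------------
# the composed analysis


def run_differential(
    data: MethylCounts | BetaMatrix,
    sheet: pd.DataFrame,
    config: Config | None = None,
    covariates: tuple[str, ...] = ("group", "age", "sex", "pmi", "batch"),
    interactions: tuple[tuple[str, str], ...] = (),
    contrasts: dict[str, str | dict[str, float]] | None = None,
    use_surrogates: bool = True,
    shrink_factor: float | None = None,
) -> dict[str, pd.DataFrame]:
    """Full per-cytosine analysis for one or more contrasts.

    Returns a mapping contrast name -> result table with columns chrom, pos,
    strand, context, beta_m, pct_change, sigma, df_resid, t, p, q, direction.
    Significance downstream is q < config.fdr_q.
    """
    config = config or Config()
    if isinstance(data, MethylCounts):
        B = data.beta(min_coverage=1)
    else:
        B = data
    if shrink_factor is None:
        has_cph = (B.keys["context"] == "CpH").any()
        shrink_factor = config.shrink_factor_cph if has_cph else config.shrink_factor
    m = beta_to_m(B.B, shrink_factor)

    sheet = sheet.reset_index(drop=True)
    X = design_matrix(sheet, covariates, interactions)
    if use_surrogates:
        sv = estimate_surrogates(m, X, config.sv_var_threshold)
        if sv.k:
            X = pd.concat([X, sv.as_frame().set_axis(X.index)], axis=1)
    if contrasts is None:
        contrasts = {"group": "group"}

    fit = fit_robust(m, X, max_iter=config.irls_max_iter)
    d0, s02 = estimate_prior_variance(fit.sigma**2, fit.df_resid)

    results: dict[str, pd.DataFrame] = {}
    for name, spec in contrasts.items():
        cvec = contrast_vector(X, spec)
        effect = fit.coef @ cvec
        se_unscaled = np.sqrt(np.einsum("p,gpq,q->g", cvec, fit.cov_unscaled,
                                        cvec))
        mod = moderate_ebayes(effect, se_unscaled, fit.sigma, fit.df_resid,
                              d0=d0, s02=s02)
        pct = percent_change(fit, cvec)
        effect = np.where(fit.ok, effect, np.nan)
        tab = B.keys.copy()
        tab["beta_m"] = effect
        tab["pct_change"] = pct
        tab["sigma"] = fit.sigma
        tab["df_resid"] = fit.df_resid
        tab["t"] = mod["t"].to_numpy()
        tab["p"] = mod["p"].to_numpy()
        tab["q"] = adjust_bh(mod["p"].to_numpy())
        tab["direction"] = np.sign(np.nan_to_num(effect)).astype(int)
        tab.attrs["d0"] = d0
        tab.attrs["s02"] = s02
        tab.attrs["design_columns"] = list(X.columns)
        results[name] = tab
    return results
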