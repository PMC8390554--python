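"""Call-matrix QC and normalisation chain.

Stage order: coverage filter -> replicate QC/merge -> call-rate / all-zero /
SNP-mask site filters -> (optional) quantile normalisation -> stable-site
filter -> PCA sample-outlier removal.  The stable-site pass runs after
normalisation; every removal is tallied in a :class:`QCReport` whose counts
telescope (before - removed = after).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    BetaMatrix,
    Config,
    MethylCounts,
    PanelAnnotation,
    ValidationError,
)


@dataclass
class QCReport:
    """Per-stage exclusion log; counts before/after each stage telescope."""

    excluded_samples: list[tuple[str, str]] = field(default_factory=list)
    removed_sites: list[tuple[str, int]] = field(default_factory=list)
    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, before: int, removed: int) -> None:
        self.stages.append(
            {"stage": name, "before": before, "removed": removed,
             "after": before - removed}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)


def coverage_filter(counts: MethylCounts, min_coverage: int) -> MethylCounts:
    """Mark cells with read depth below ``min_coverage`` as missing."""
    if min_coverage < 1:
        raise ValidationError("min_coverage must be >= 1")
    cov = counts.coverage
    with np.errstate(invalid="ignore"):
        drop = ~(cov >= min_coverage)  # NaN coverage stays missing
    M = counts.M.copy()
    U = counts.U.copy()
    M[drop] = np.nan
    U[drop] = np.nan
    return MethylCounts(counts.keys, counts.samples, M, U)


def _pairwise_r(B: np.ndarray, i: int, j: int) -> float:
    both = ~np.isnan(B[:, i]) & ~np.isnan(B[:, j])
    if both.sum() < 3:
        return np.nan
    x, y = B[both, i], B[both, j]
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def merge_replicates(
    counts: MethylCounts,
    sheet: pd.DataFrame,
    min_r: float = 0.9,
    report: QCReport | None = None,
) -> tuple[MethylCounts, pd.DataFrame, QCReport]:
    """Check replicate concordance, then collapse replicate groups.

    Samples whose beta-value Pearson r with their replicate partner is
    <= ``min_r`` are excluded; the member with the lower median coverage is
    dropped (both are reported).  Surviving groups are merged by averaging M
    and U cell-wise over non-missing members (rounded half-up).
    """
    report = report or QCReport()
    if "replicate_group" not in sheet.columns:
        report.add_stage("replicate_merge", counts.n_samples, 0)
        return counts, sheet, report
    sheet = sheet.reset_index(drop=True)
    B = counts.beta(min_coverage=1).B
    cov = counts.coverage
    order = {s: k for k, s in enumerate(counts.samples)}

    excluded: set[str] = set()
    groups: dict[str, list[str]] = {}
    for _, row in sheet.iterrows():
        g = row.get("replicate_group", "")
        if isinstance(g, str) and g:
            groups.setdefault(g, []).append(row["sample_id"])

    import warnings

    for g, members in groups.items():
        if len(members) < 2:
            warnings.warn(f"replicate group {g!r} has a single member; "
                          "passed through unchanged", stacklevel=2)
            continue
        idx = [order[s] for s in members]
        rs = [_pairwise_r(B, i, j) for k, i in enumerate(idx) for j in idx[k + 1:]]
        worst = np.nanmin(rs) if rs and not np.all(np.isnan(rs)) else np.nan
        if np.isnan(worst):
            warnings.warn(f"replicate group {g!r}: correlation not assessable; "
                          "members retained", stacklevel=2)
            continue
        if worst <= min_r:
            med = [np.nanmedian(cov[:, i]) for i in idx]
            victim = members[int(np.argmin(med))]
            excluded.add(victim)
            for s in members:
                report.excluded_samples.append(
                    (s, f"low replicate r={worst:.3f} in group {g} "
                        f"(excluded: {victim})"))

    keep_sheet = sheet[~sheet["sample_id"].isin(excluded)].reset_index(drop=True)
    # collapse remaining groups to a single column
    new_cols: list[str] = []
    M_cols, U_cols, rows = [], [], []
    done_groups: set[str] = set()
    for _, row in keep_sheet.iterrows():
        s = row["sample_id"]
        g = row.get("replicate_group", "")
        if isinstance(g, str) and g and g in groups:
            if g in done_groups:
                continue
            done_groups.add(g)
            members = [m for m in groups[g] if m not in excluded]
            idx = [order[m] for m in members]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                m_avg = np.nanmean(counts.M[:, idx], axis=1)
                u_avg = np.nanmean(counts.U[:, idx], axis=1)
            M_cols.append(np.floor(m_avg + 0.5))
            U_cols.append(np.floor(u_avg + 0.5))
            new_cols.append(members[0])
            rows.append(row.to_dict() | {"sample_id": members[0]})
        else:
            M_cols.append(counts.M[:, order[s]])
            U_cols.append(counts.U[:, order[s]])
            new_cols.append(s)
            rows.append(row.to_dict())
    merged = MethylCounts(counts.keys, new_cols,
                          np.column_stack(M_cols), np.column_stack(U_cols))
    new_sheet = pd.DataFrame(rows).reset_index(drop=True)
    report.add_stage("replicate_merge", counts.n_samples,
                     counts.n_samples - merged.n_samples)
    return merged, new_sheet, report


def site_filters(
    counts: MethylCounts,
    annotation: PanelAnnotation | None = None,
    min_call_rate: float = 0.7,
    report: QCReport | None = None,
) -> tuple[MethylCounts, QCReport]:
    """Pre-normalisation site filters, applied in order:

    1. call rate: sites observed in < ``min_call_rate`` of samples removed;
    2. all-zero: sites whose every observed call is 0% removed;
    3. SNP mask: sites inside the supplied mask intervals removed.
    """
    report = report or QCReport()
    B = counts.beta(min_coverage=1).B

    call_rate = np.mean(~np.isnan(B), axis=1)
    keep = call_rate >= min_call_rate
    for i in np.flatnonzero(~keep):
        report.removed_sites.append(("call_rate", i))
    report.add_stage("call_rate", counts.n_sites, int((~keep).sum()))
    counts = counts.subset_sites(keep)
    B = B[keep]

    with np.errstate(invalid="ignore"):
        all_zero = np.nanmax(B, axis=1) == 0
    observed_any = np.any(~np.isnan(B), axis=1)
    all_zero = all_zero & observed_any
    report.add_stage("all_zero", counts.n_sites, int(all_zero.sum()))
    counts = counts.subset_sites(~all_zero)

    if annotation is not None and annotation.snp_mask is not None \
            and len(annotation.snp_mask):
        inside = annotation.snp_mask.contains(
            counts.keys["chrom"].to_numpy(), counts.keys["pos"].to_numpy())
        report.add_stage("snp_mask", counts.n_sites, int(inside.sum()))
        counts = counts.subset_sites(~inside)
    else:
        report.add_stage("snp_mask", counts.n_sites, 0)
    if counts.n_sites == 0:
        raise ValidationError("no sites remain after site filtering")
    return counts, report


def stable_site_filter(
    counts: MethylCounts,
    stable_fraction: float = 0.5,
    report: QCReport | None = None,
) -> tuple[MethylCounts, QCReport]:
    """Remove sites with stable calls (0%, 100%, and/or missing) in
    ``stable_fraction`` or more of the samples (boundary inclusive)."""
    report = report or QCReport()
    B = counts.beta(min_coverage=1).B
    stable = np.isnan(B) | (B == 0.0) | (B == 1.0)
    frac = stable.mean(axis=1)
    drop = frac >= stable_fraction
    report.add_stage("stable_site", counts.n_sites, int(drop.sum()))
    counts = counts.subset_sites(~drop)
    if counts.n_sites == 0:
        raise ValidationError("no sites remain after stable-site filtering")
    return counts, report


def quantile_normalize(counts: MethylCounts) -> MethylCounts:
    """Quantile-normalise the M and U matrices independently.

    Each column's observed values are replaced by the reference distribution
    (the cross-column mean of sorted values) evaluated at the value's average
    rank; ties receive the average of their reference quantiles.  Missing
    cells are skipped and restored missing.  Results are rounded half-up.
    """

    def _qn(X: np.ndarray) -> np.ndarray:
        obs_cols = [np.sort(X[~np.isnan(X[:, j]), j]) for j in range(X.shape[1])]
        if any(len(c) < 1 for c in obs_cols):
            raise ValidationError("column with no observed values")

        def ref(q: np.ndarray) -> np.ndarray:
            # mean over columns of each column's empirical quantile function
            # (midpoint plotting positions); equal column sizes reduce this
            # to the classic mean-of-sorted-columns reference
            acc = np.zeros_like(q, dtype=float)
            for c in obs_cols:
                xp = (np.arange(len(c)) + 0.5) / len(c)
                acc += np.interp(q, xp, c)
            return acc / len(obs_cols)

        out = np.full_like(X, np.nan)
        for j in range(X.shape[1]):
            col = X[~np.isnan(X[:, j]), j]
            nj = len(col)
            order = np.argsort(col, kind="stable")
            vals = np.empty(nj)
            vals[order] = ref((np.arange(nj) + 0.5) / nj)
            # ties: average of the tied positions' reference quantiles
            s = pd.Series(vals).groupby(pd.Series(col)).transform("mean")
            out[~np.isnan(X[:, j]), j] = np.floor(s.to_numpy() + 0.5)
        return out

    return MethylCounts(counts.keys, counts.samples, _qn(counts.M), _qn(counts.U))


def pca_outliers(
    B: BetaMatrix,
    outlier_sd: float = 3.0,
    report: QCReport | None = None,
) -> tuple[list[str], QCReport]:
    """Flag samples deviating > ``outlier_sd`` SDs from the mean of either of
    the first two principal components of the beta matrix.

    Missing cells are mean-imputed per site solely for this PCA.  Single pass.
    """
    report = report or QCReport()
    if len(B.samples) < 4:
        raise ValidationError("PCA outlier screen needs at least 4 samples")
    X = B.B.copy()
    observed = ~np.isnan(X)
    if int(observed.any(axis=1).sum()) < 3:
        raise ValidationError("fewer than 3 sites with any observed values")
    row_mean = np.nanmean(np.where(observed, X, np.nan), axis=1)
    X = np.where(observed, X, row_mean[:, None])
    keep_rows = ~np.isnan(row_mean)
    X = X[keep_rows]
    X = X - X.mean(axis=1, keepdims=True)
    # samples as rows for the score decomposition
    U_, S, _ = np.linalg.svd(X.T, full_matrices=False)
    scores = U_[:, :2] * S[:2]
    flagged: set[int] = set()
    for pc in range(min(2, scores.shape[1])):
        s = scores[:, pc]
        sd = np.std(s, ddof=1)
        if sd == 0:
            continue
        dev = np.abs(s - s.mean()) / sd
        flagged.update(np.flatnonzero(dev > outlier_sd).tolist())
    names = [B.samples[j] for j in sorted(flagged)]
    for s in names:
        report.excluded_samples.append((s, "PCA outlier"))
    report.add_stage("pca_outliers", len(B.samples), len(names))
    return names, report


def run_preprocess(
    counts: MethylCounts,
    sheet: pd.DataFrame,
    annotation: PanelAnnotation | None = None,
    config: Config | None = None,
) -> tuple[MethylCounts, BetaMatrix, pd.DataFrame, QCReport]:
    """Run the full QC chain; returns filtered counts, beta matrix, the
    updated sample sheet, and the telescoping QC report."""
    config = config or Config()
    report = QCReport()
    counts = coverage_filter(counts, config.min_coverage)
    counts, sheet, report = merge_replicates(
        counts, sheet, config.replicate_min_r, report)
    counts, report = site_filters(counts, annotation,
                                  config.min_call_rate, report)
    if config.normalize:
        counts = quantile_normalize(counts)
    counts, report = stable_site_filter(counts, config.stable_fraction, report)
    B = counts.beta(min_coverage=1)
    bad, report = pca_outliers(B, config.outlier_sd, report)
    if bad:
        keep = [s for s in counts.samples if s not in set(bad)]
        counts = counts.subset_samples(keep)
        sheet = sheet[~sheet["sample_id"].isin(bad)].reset_index(drop=True)
        B = counts.beta(min_coverage=1)
    from .types import validate_sample_sheet

    sheet = validate_sample_sheet(sheet, counts.samples)
    return counts, B, sheet, report
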