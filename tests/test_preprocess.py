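import numpy as np
import pandas as pd
import pytest

from methylpanel import Config, ValidationError
from methylpanel.preprocess import (
    coverage_filter,
    merge_replicates,
    pca_outliers,
    quantile_normalize,
    run_preprocess,
    site_filters,
    stable_site_filter,
)
from methylpanel.simulate import SimConfig, simulate_null, simulate_panel

from conftest import make_counts


def test_coverage_filter_boundary():
    counts = make_counts([[10, 10, 10]], [[19, 20, 0]])  # cov 29, 30, 10
    out = coverage_filter(counts, 30)
    assert np.isnan(out.M[0, 0])          # cov 29 -> missing
    assert out.M[0, 1] == 10              # cov 30 retained, unchanged
    assert np.isnan(out.M[0, 2])
    out1 = coverage_filter(counts, 1)
    assert not np.isnan(out1.M).any()


def test_identical_replicates_merge_to_same_column():
    M = np.array([[10.0, 10.0], [3.0, 3.0], [25.0, 25.0], [14.0, 14.0]])
    U = np.array([[20.0, 20.0], [27.0, 27.0], [5.0, 5.0], [16.0, 16.0]])
    counts = make_counts(M, U, samples=["a", "a2"])
    sheet = pd.DataFrame({"sample_id": ["a", "a2"],
                          "group": ["case", "case"],
                          "replicate_group": ["R1", "R1"]})
    merged, new_sheet, report = merge_replicates(counts, sheet, 0.9)
    assert merged.n_samples == 1
    np.testing.assert_array_equal(merged.M[:, 0], M[:, 0])
    assert not report.excluded_samples


def test_anticorrelated_replicates_trigger_exclusion(rng):
    b = rng.uniform(0.1, 0.9, size=50)
    cov = 100
    M = np.column_stack([np.round(b * cov), np.round((1 - b) * cov)])
    U = cov - M
    counts = make_counts(M, U, samples=["a", "a2"])
    sheet = pd.DataFrame({"sample_id": ["a", "a2"],
                          "group": ["case", "case"],
                          "replicate_group": ["R1", "R1"]})
    merged, new_sheet, report = merge_replicates(counts, sheet, 0.9)
    assert merged.n_samples == 1
    assert report.excluded_samples  # both members reported


def test_merged_counts_equal_rounded_mean(rng):
    M = rng.integers(0, 50, size=(30, 3)).astype(float)
    U = rng.integers(1, 50, size=(30, 3)).astype(float)
    # make the three columns strongly correlated so they pass QC
    M[:, 1] = np.clip(M[:, 0] + rng.integers(-2, 3, size=30), 0, None)
    M[:, 2] = np.clip(M[:, 0] + rng.integers(-2, 3, size=30), 0, None)
    U[:, 1] = U[:, 0]
    U[:, 2] = U[:, 0]
    counts = make_counts(M, U, samples=["a", "b", "c"])
    sheet = pd.DataFrame({"sample_id": ["a", "b", "c"],
                          "group": "case",
                          "replicate_group": ["R1", "R1", "R1"]})
    merged, *_ = merge_replicates(counts, sheet, 0.9)
    np.testing.assert_array_equal(merged.M[:, 0],
                                  np.floor(M.mean(axis=1) + 0.5))


def test_site_filters_call_rate_boundary():
    n = 100
    M = np.full((2, n), 10.0)
    U = np.full((2, n), 10.0)
    M[0, 69:] = np.nan  # observed in 69 of 100 -> below 0.7
    U[0, 69:] = np.nan
    counts = make_counts(M, U)
    out, report = site_filters(counts, None, 0.7)
    assert out.n_sites == 1


def test_site_filters_remove_all_zero_sites():
    M = np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 3.0]])
    U = np.array([[10.0, 9.0, 8.0], [9.0, 8.0, 7.0]])
    out, _ = site_filters(make_counts(M, U), None, 0.5)
    assert out.n_sites == 1
    assert out.M[0, 0] == 1


def test_stable_site_boundary_is_inclusive():
    # exactly 50% of samples fully methylated -> removed
    M = np.array([[10.0, 10.0, 5.0, 6.0], [5.0, 6.0, 5.0, 6.0]])
    U = np.array([[0.0, 0.0, 5.0, 4.0], [5.0, 4.0, 5.0, 4.0]])
    out, _ = stable_site_filter(make_counts(M, U), 0.5)
    assert out.n_sites == 1


def test_quantile_normalize_permuted_columns_share_multiset(rng):
    vals = rng.integers(5, 200, size=40).astype(float)
    M = np.column_stack([vals, rng.permutation(vals), rng.permutation(vals)])
    counts = make_counts(M, np.full_like(M, 7.0))
    out = quantile_normalize(counts)
    ref = np.sort(out.M[:, 0])
    for j in (1, 2):
        np.testing.assert_array_equal(np.sort(out.M[:, j]), ref)
    # and U columns (identical here) are a fixed point after rounding
    np.testing.assert_array_equal(out.U, counts.U)


def test_quantile_normalize_hand_computed_3x3():
    # columns sorted: (1,4,7), (2,5,8), (3,6,9); reference = (2,5,8)
    M = np.array([[1.0, 8.0, 6.0], [4.0, 2.0, 9.0], [7.0, 5.0, 3.0]])
    counts = make_counts(M, np.full_like(M, 1.0))
    out = quantile_normalize(counts)
    expect = np.array([[2.0, 8.0, 5.0], [5.0, 2.0, 8.0], [8.0, 5.0, 2.0]])
    np.testing.assert_array_equal(out.M, expect)


def test_quantile_normalize_preserves_rank_order(rng):
    M = rng.integers(0, 100, size=(50, 4)).astype(float)
    U = rng.integers(1, 100, size=(50, 4)).astype(float)
    M[rng.random(M.shape) < 0.1] = np.nan
    U[np.isnan(M)] = np.nan
    out = quantile_normalize(make_counts(M, U))
    for j in range(4):
        obs = ~np.isnan(M[:, j])
        orig_order = np.argsort(M[obs, j], kind="stable")
        new = out.M[obs, j][orig_order]
        assert (np.diff(new) >= 0).all()


def test_pca_flags_planted_outlier_exactly():
    cfg = SimConfig(n_genes=40, n_outlier_samples=1, outlier_shift_sd=8.0,
                    seed=6)
    counts, sheet, _, truth = simulate_panel(cfg)
    bad, _ = pca_outliers(counts.beta(1), 3.0)
    assert bad == truth.outlier_samples


def test_pca_treats_duplicated_sample_as_its_twin():
    """A duplicated sample sits at zero deviation from its twin's PC
    position, so the two always share the same flag status."""
    counts, sheet, _, _ = simulate_null(SimConfig(n_genes=30, seed=7))
    B = counts.beta(1)
    B2 = type(B)(B.keys, B.samples + ["dup"],
                 np.column_stack([B.B, B.B[:, 0]]))
    bad, _ = pca_outliers(B2, 3.0)
    assert ("dup" in bad) == (B.samples[0] in bad)


def test_pca_rarely_flags_homogeneous_null():
    clean = 0
    for seed in range(8):
        counts, *_ = simulate_null(SimConfig(n_genes=25, seed=100 + seed))
        bad, _ = pca_outliers(counts.beta(1), 3.0)
        clean += not bad
    assert clean >= 7


def test_full_chain_telescopes_and_excludes_outlier():
    cfg = SimConfig(n_genes=40, n_replicate_pairs=2, n_outlier_samples=1,
                    outlier_shift_sd=8.0, seed=19)
    counts, sheet, annotation, truth = simulate_panel(cfg)
    out, B, sheet2, report = run_preprocess(counts, sheet, annotation, Config())
    stages = report.to_frame()
    assert (stages["before"] - stages["removed"] == stages["after"]).all()
    assert truth.outlier_samples[0] not in out.samples
    assert out.n_samples == len(sheet2)


def test_empty_result_raises():
    M = np.full((3, 10), np.nan)
    counts = make_counts(M, M.copy())
    with pytest.raises(ValidationError):
        site_filters(counts, None, 0.7)
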