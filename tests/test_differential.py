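import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from methylpanel import Config
from methylpanel.differential import (
    adjust_bh,
    beta_to_m,
    contrast_vector,
    design_matrix,
    estimate_prior_variance,
    estimate_surrogates,
    fit_robust,
    m_to_beta,
    moderate_ebayes,
    percent_change,
    run_differential,
)
from methylpanel.simulate import SimConfig, simulate_null, simulate_panel


# ---------------------------------------------------------------------------
# transforms


def test_beta_to_m_center_and_extremes():
    assert beta_to_m(0.5, 1000) == pytest.approx(0.0)
    assert beta_to_m(0.5, 37) == pytest.approx(0.0)
    # B = 1 at f = 1000: B' = 0.9995, m = log2(0.9995/0.0005) = log2(1999)
    assert beta_to_m(1.0, 1000) == pytest.approx(np.log2(1999))
    assert beta_to_m(0.0, 1000) == pytest.approx(-np.log2(1999))


def test_m_transform_round_trip_and_shrink_bound():
    B = np.linspace(0, 1, 201)
    for f in (2, 100, 1000, 2000):
        m = beta_to_m(B, f)
        assert (np.diff(m) > 0).all()  # strictly increasing
        Bp = m_to_beta(m)
        # the inverse recovers the shrunk value, within 0.5/f of B
        np.testing.assert_allclose(Bp, (B * (f - 1) + 0.5) / f, atol=1e-12)
        assert np.max(np.abs(Bp - B)) <= 0.5 / f + 1e-12
    assert m_to_beta(0.0) == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# BH


def brute_force_bh(p):
    """Textbook step-up rule by direct enumeration."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        q[i] = prev
    return q


def test_bh_hand_example_and_single_p():
    np.testing.assert_allclose(adjust_bh(np.array([0.01, 0.02, 0.03, 0.04])),
                               [0.04, 0.04, 0.04, 0.04])
    np.testing.assert_allclose(adjust_bh(np.array([0.3])), [0.3])


@given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
@settings(deadline=None, max_examples=100, derandomize=True)
def test_bh_matches_brute_force_enumeration(plist):
    p = np.array(plist)
    q = adjust_bh(p)
    np.testing.assert_allclose(q, brute_force_bh(p), atol=1e-12)
    assert (q >= p - 1e-12).all() and (q <= 1 + 1e-12).all()


def test_bh_permutation_invariance(rng):
    p = rng.uniform(size=50)
    perm = rng.permutation(50)
    np.testing.assert_allclose(adjust_bh(p)[perm], adjust_bh(p[perm]))


# ---------------------------------------------------------------------------
# robust fitting


def _design(n, rng):
    sheet = pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(n)],
        "group": ["case"] * (n // 2) + ["control"] * (n - n // 2),
        "age": rng.uniform(40, 90, n),
    })
    return design_matrix(sheet, ("group", "age"))


def test_clean_data_reproduces_ols_exactly(rng):
    n = 30
    X = _design(n, rng)
    A = X.to_numpy()
    beta_true = np.array([1.0, 0.5, 0.01])
    # sign-balanced noise with max/MAD well below 1.345*1.4826, so every
    # residual stays inside c*scale and the Huber weights are all one
    signs = np.resize([1.0, -1.0], n)
    noise = signs[None, :] * rng.uniform(0.5, 1.0, size=(20, n))
    Y = (A @ beta_true)[None, :] + noise
    fit = fit_robust(Y, X)
    ols = np.linalg.lstsq(A, Y.T, rcond=None)[0].T
    np.testing.assert_allclose(fit.coef, ols, atol=1e-8)


def test_gross_outlier_resisted_in_most_fixtures(rng):
    wins = 0
    trials = 60
    n = 30
    for _ in range(trials):
        x = rng.uniform(-1, 1, n)
        X = pd.DataFrame({"Intercept": np.ones(n), "x": x})
        y = 2.0 * x + rng.normal(0, 0.3, n)
        slope_clean = np.polyfit(x, y, 1)[0]
        y_cont = y.copy()
        y_cont[0] += 25.0
        slope_cont = np.polyfit(x, y_cont, 1)[0]
        fit = fit_robust(y_cont[None, :], X)
        if abs(fit.coef[0, 1] - slope_clean) < abs(slope_cont - slope_clean):
            wins += 1
    assert wins / trials >= 0.95


def test_planted_effect_recovered_within_20_percent():
    cfg = SimConfig(n_genes=25, cytosines_per_gene=(10, 10), coverage_mean=100,
                    frac_affected_genes=0.5, frac_affected_cytosines=1.0,
                    hyper_fraction=0.5, seed=31)
    counts, sheet, _, truth = simulate_panel(cfg)
    fits = run_differential(counts, sheet, Config(), use_surrogates=False)["group"]
    tr = truth.sites.merge(fits, on=["chrom", "pos", "strand", "context"])
    aff = tr["delta"] != 0
    assert aff.sum() >= 100
    ratio = (tr.loc[aff, "pct_change"] / tr.loc[aff, "delta"]).mean()
    assert 0.8 <= ratio <= 1.2


def test_rank_deficient_cytosines_skipped(rng):
    n = 12
    X = _design(n, rng)
    Y = rng.normal(size=(3, n))
    Y[1, 2:] = np.nan  # too few complete cases
    fit = fit_robust(Y, X)
    assert fit.ok[0] and fit.ok[2] and not fit.ok[1]
    assert fit.skipped == [1]


# ---------------------------------------------------------------------------
# empirical Bayes


def test_equal_variances_shrink_to_themselves():
    sigma = np.full(50, 1.3)
    df = np.full(50, 20.0)
    eff = np.ones(50)
    se = np.ones(50)
    out = moderate_ebayes(eff, se, sigma, df)
    np.testing.assert_allclose(out["s2_post"], 1.3**2, rtol=1e-3)


def test_d0_zero_limit_gives_ordinary_t(rng):
    sigma = rng.uniform(0.5, 2.0, 40)
    df = np.full(40, 10.0)
    eff = rng.normal(size=40)
    se = np.ones(40)
    out = moderate_ebayes(eff, se, sigma, df, d0=1e-9, s02=1.0)
    np.testing.assert_allclose(out["t"], eff / sigma, rtol=1e-4)
    expect_p = 2 * stats.t.sf(np.abs(eff / sigma), 10.0)
    np.testing.assert_allclose(out["p"], expect_p, rtol=1e-3)


def test_prior_df_recovered_from_scaled_inv_chisq(rng):
    d0_true, s02_true = 8.0, 1.5
    df = np.full(5000, 20.0)
    s2 = s02_true * d0_true / rng.chisquare(d0_true, 5000) \
        * rng.chisquare(20, 5000) / 20.0
    d0, s02 = estimate_prior_variance(s2, df)
    assert abs(d0 - d0_true) / d0_true < 0.25
    assert abs(s02 - s02_true) / s02_true < 0.25


def test_degenerate_identical_variances_hit_cap():
    d0, s02 = estimate_prior_variance(np.full(100, 2.0), np.full(100, 15.0))
    assert d0 == pytest.approx(1e7)


# ---------------------------------------------------------------------------
# surrogate variables


def test_surrogate_recovers_hidden_batch():
    cfg = SimConfig(n_genes=60, n_batches=2, batch_sd=6.0, seed=23,
                    frac_affected_genes=0.0)
    counts, sheet, _, truth = simulate_panel(cfg)
    B = counts.beta(1)
    m = beta_to_m(B.B, 1000)
    X = design_matrix(sheet, ("group", "age"))  # batch NOT in the design
    sv = estimate_surrogates(m, X, 0.05)
    assert sv.k >= 1
    batch = sheet["batch"].to_numpy(dtype=float)
    r = np.corrcoef(sv.scores[:, 0], batch)[0, 1]
    assert abs(r) > 0.8


def test_threshold_one_yields_no_surrogates():
    counts, sheet, _, _ = simulate_null(SimConfig(n_genes=20, seed=3))
    m = beta_to_m(counts.beta(1).B, 1000)
    X = design_matrix(sheet, ("group",))
    assert estimate_surrogates(m, X, 1.0).k == 0


def test_modelled_structure_leaves_no_surrogates():
    """With the group effect modelled and no latent structure, no residual
    PC clears the 5% share at cohort-scale sample counts (the chance share
    of the top noise PC shrinks like (1 + sqrt(rank/G))^2 / rank)."""
    hits = 0
    for seed in range(10):
        counts, sheet, _, _ = simulate_panel(
            SimConfig(n_genes=100, n_case=50, n_control=50, seed=300 + seed))
        m = beta_to_m(counts.beta(1).B, 1000)
        X = design_matrix(sheet)
        hits += estimate_surrogates(m, X, 0.05).k == 0
    assert hits >= 9


# ---------------------------------------------------------------------------
# percentage-point effects


def test_percent_change_closed_form_two_group():
    """Fitted group means m=0 vs m=1 give 100*(2/3 - 1/2) points."""
    n = 20
    sheet = pd.DataFrame({"sample_id": [f"S{i}" for i in range(n)],
                          "group": ["case"] * 10 + ["control"] * 10})
    X = design_matrix(sheet, ("group",))
    y = np.where(X["group"].to_numpy() == 1, 1.0, 0.0)[None, :]
    fit = fit_robust(y, X)
    pct = percent_change(fit, contrast_vector(X, "group"))
    assert pct[0] == pytest.approx(100 * (2 / 3 - 1 / 2), abs=1e-6)


def test_percent_change_zero_for_null_fit():
    n = 16
    sheet = pd.DataFrame({"sample_id": [f"S{i}" for i in range(n)],
                          "group": ["case"] * 8 + ["control"] * 8})
    X = design_matrix(sheet, ("group",))
    y = np.full((2, n), 0.37)
    fit = fit_robust(y, X)
    pct = percent_change(fit, contrast_vector(X, "group"))
    np.testing.assert_allclose(pct, 0.0, atol=1e-8)


# ---------------------------------------------------------------------------
# composed analysis


def test_interaction_contrast_is_slope_difference(small_sim):
    _, counts, sheet, annotation, _ = small_sim
    res = run_differential(
        counts.beta(30), sheet, Config(),
        interactions=(("group", "age"),),
        contrasts={"age_control": {"age": 1.0},
                   "age_case": {"age": 1.0, "group:age": 1.0},
                   "age_diff": {"group:age": 1.0}},
        use_surrogates=False)
    diff = res["age_case"]["beta_m"] - res["age_control"]["beta_m"]
    np.testing.assert_allclose(diff, res["age_diff"]["beta_m"], atol=1e-10)


def test_direction_matches_sign_of_effect(small_fits):
    _, fits, _, _ = small_fits
    ok = fits["beta_m"].notna()
    np.testing.assert_array_equal(fits.loc[ok, "direction"],
                                  np.sign(fits.loc[ok, "beta_m"]))
    assert (fits.loc[ok, "q"] >= fits.loc[ok, "p"] - 1e-12).all()


def test_pipeline_reruns_after_dropping_a_sample(small_sim):
    _, counts, sheet, annotation, _ = small_sim
    keep = counts.samples[1:]
    sub = counts.subset_samples(keep)
    res = run_differential(sub, sheet[sheet.sample_id.isin(keep)],
                           Config())["group"]
    assert len(res) == sub.n_sites
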