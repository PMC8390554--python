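import math

import numpy as np
import pandas as pd
import pytest

from methylpanel import Config, ValidationError, run_differential, run_preprocess
from methylpanel.enrichment import (
    directional_enrichment,
    element_enrichment,
    fisher_or,
    gene_stats,
    geneset_overlap,
    pathway_enrichment,
    top_sites_element_concordance,
    tss_bin_enrichment,
)
from methylpanel.simulate import SimConfig, simulate_panel
from methylpanel.types import IntervalSet, PanelAnnotation


def enumeration_p(a, b, c, d, alternative="two-sided"):
    """Exact hypergeometric p by exhaustive enumeration over the support."""
    n1, n2, m1 = a + b, c + d, a + c
    lo, hi = max(0, m1 - n2), min(m1, n1)
    pmf = {}
    for x in range(lo, hi + 1):
        pmf[x] = (math.comb(n1, x) * math.comb(n2, m1 - x)
                  / math.comb(n1 + n2, m1))
    if alternative == "greater":
        return sum(p for x, p in pmf.items() if x >= a)
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-12))


def test_fisher_identical_margins_gives_or_one():
    res = fisher_or((10, 90, 10, 90))
    assert res.or_value == pytest.approx(1.0)
    assert res.p == pytest.approx(1.0)
    assert res.ci_low <= res.or_value <= res.ci_high


def test_fisher_diagonal_table_matches_enumeration():
    res = fisher_or((5, 0, 0, 5))
    assert res.p == pytest.approx(2 / 252, abs=1e-12)
    assert np.isinf(res.or_value)


def test_fisher_matches_enumeration_on_random_tables(rng):
    for _ in range(200):
        a, b, c, d = rng.integers(0, 16, size=4)
        if (a + b == 0) or (c + d == 0) or (a + b + c + d == 0):
            continue
        for alt in ("two-sided", "greater"):
            got = fisher_or((a, b, c, d), alt).p
            assert got == pytest.approx(enumeration_p(a, b, c, d, alt),
                                        abs=1e-10)


def test_fisher_all_zero_rejected():
    with pytest.raises(ValidationError):
        fisher_or((0, 0, 0, 0))


def _fits_frame(q, direction, pct=None, p=None, pos=None):
    n = len(q)
    return pd.DataFrame({
        "chrom": "chr1",
        "pos": pos if pos is not None else np.arange(1, n + 1) * 10,
        "strand": "+", "context": "CpG",
        "beta_m": direction.astype(float),
        "pct_change": pct if pct is not None else direction * 5.0,
        "p": p if p is not None else q,
        "q": q,
        "direction": direction,
    })


def test_directional_all_hyper_is_infinite():
    q = np.array([0.01] * 5 + [0.5] * 20)
    direction = np.array([1] * 5 + [1] * 10 + [-1] * 10)
    res = directional_enrichment(_fits_frame(q, direction))
    assert np.isinf(res.or_value)


def test_directional_no_significant_sites():
    q = np.full(10, 0.9)
    res = directional_enrichment(_fits_frame(q, np.ones(10, dtype=int)))
    assert res.n_fg == 0 and res.p == 1.0


def test_directional_recovers_planted_hyper_bias():
    cfg = SimConfig(n_genes=80, hyper_fraction=0.7, seed=41)
    counts, sheet, annotation, _ = simulate_panel(cfg)
    counts, B, sheet, _ = run_preprocess(counts, sheet, annotation, Config())
    fits = run_differential(B, sheet, Config())["group"]
    res = directional_enrichment(fits)
    assert res.or_value > 1 and res.p < 0.05


def _toy_annotation():
    genes = pd.DataFrame({
        "gene_id": ["GA", "GB"], "chrom": "chr1", "tss": [1000, 5000],
        "strand": "+", "window_bp": 1500,
        "pathways": ["lysosome", "autophagy"], "gwas_flag": False,
    })
    elements = {
        "promoter": IntervalSet(pd.DataFrame(
            {"chrom": "chr1", "start": [800, 4800], "end": [1100, 5100]})),
        "exon": IntervalSet(pd.DataFrame(
            {"chrom": "chr1", "start": [1200], "end": [1400]})),
    }
    return PanelAnnotation(genes=genes, elements=elements)


def test_element_enrichment_counts_membership_per_class():
    ann = _toy_annotation()
    # one site inside both promoter and exon ranges -> counted in each class
    pos = np.array([900, 1250, 1300, 4900, 2000, 2100])
    q = np.array([0.01, 0.01, 0.5, 0.5, 0.5, 0.5])
    fits = _fits_frame(q, np.ones(6, dtype=int), pos=pos)
    out = element_enrichment(fits, ann).set_index("label")
    assert out.loc["promoter", "n_fg"] == 2
    # exon counts are independent of promoter counts
    assert out.loc["exon"].notna()["or"] or np.isnan(out.loc["exon", "or"])


def test_tss_bin_boundary_is_half_open():
    ann = _toy_annotation()
    # site at 25000: nearest TSS is GB (5000), distance exactly 20000 -> bin 1
    pos = np.array([1000, 25000, 1010, 980, 990, 1020])
    q = np.array([0.01, 0.01, 0.5, 0.5, 0.5, 0.5])
    fits = _fits_frame(q, np.ones(6, dtype=int), pos=pos)
    out = tss_bin_enrichment(fits, ann, bin_bp=20000,
                             strata={"all": ["GA", "GB"]})
    d0 = out[out["bin"] == 0]
    assert len(out[out["bin"] == 1]) == 1  # distance exactly 20000 -> bin 2
    assert d0["n_sites"].iloc[0] == 5


def test_pathway_enrichment_detects_planted_lysosome_hyper():
    cfg = SimConfig(n_genes=100, affected_pathway="lysosome",
                    frac_affected_genes=0.12, hyper_fraction=1.0, seed=43)
    counts, sheet, annotation, truth = simulate_panel(cfg)
    counts, B, sheet, _ = run_preprocess(counts, sheet, annotation, Config())
    fits = run_differential(B, sheet, Config())["group"]
    out = pathway_enrichment(fits, annotation, subset="hyper")
    out = out.set_index("label")
    assert out.loc["lysosome", "or"] > 1
    assert out.loc["lysosome", "p"] < 0.05


def test_gene_stats_majority_and_tiebreak_rules():
    ann = _toy_annotation()
    # gene GA: 3 significant sites with signs (+, +, -) -> majority +
    pos = np.array([900, 950, 1050, 1100, 4900, 4950])
    q = np.array([0.01, 0.01, 0.01, 0.6, 0.01, 0.01])
    p = np.array([0.001, 0.002, 0.003, 0.6, 0.0001, 0.01])
    direction = np.array([1, 1, -1, 1, 1, -1])
    pct = np.array([5.0, 4.0, -3.0, 1.0, 2.0, -8.0])
    fits = _fits_frame(q, direction, pct=pct, p=p, pos=pos)
    gs = gene_stats(fits, ann).set_index("gene_id")
    assert gs.loc["GA", "direction"] == 1
    # gene GB: significant signs (+, -) tie; wmfc weights -log10 p:
    # (3*2 + 2*(-8)) / 5 = -2 -> direction -
    wmfc_gb = (4 * 2.0 + 2 * (-8.0)) / 6
    assert gs.loc["GB", "wmfc"] == pytest.approx(wmfc_gb)
    assert gs.loc["GB", "direction"] == -1


def test_gene_stats_two_by_two_matches_direct_recomputation(small_fits):
    _, fits, annotation, _ = small_fits
    gs = gene_stats(fits, annotation, alpha=0.05)
    assigned = annotation.assign_genes(fits[["chrom", "pos"]])
    scored = fits["q"].notna().to_numpy()
    sig = (fits["q"] < 0.05).fillna(False).to_numpy()
    total_sig = int(sig.sum())
    for _, row in gs.sample(10, random_state=0).iterrows():
        in_gene = (assigned == row["gene_id"]).to_numpy()
        a = int((sig & in_gene).sum())
        assert a == row["sig_in"]
        assert row["sig_out"] == total_sig - a
        expect = enumeration_p(row["sig_in"], row["nonsig_in"],
                               row["sig_out"], row["nonsig_out"], "greater")
        assert row["p_one_sided"] == pytest.approx(expect, abs=1e-10)
    # sig_in sums + unassigned significant = total significant
    unassigned_sig = int((sig & assigned.isna().to_numpy()).sum())
    assert gs["sig_in"].sum() + unassigned_sig == total_sig


def test_gene_stats_order_invariance(small_fits):
    _, fits, annotation, _ = small_fits
    gs1 = gene_stats(fits, annotation)
    shuffled = fits.sample(frac=1.0, random_state=1).reset_index(drop=True)
    gs2 = gene_stats(shuffled, annotation)
    pd.testing.assert_frame_equal(
        gs1.sort_values("gene_id").reset_index(drop=True),
        gs2.sort_values("gene_id").reset_index(drop=True))


def test_geneset_overlap_counts_and_perfect_association():
    universe = {f"g{i}" for i in range(20)}
    half = {f"g{i}" for i in range(10)}
    res = geneset_overlap(half, half, universe)
    assert np.isinf(res.or_value)
    other = {f"g{i}" for i in range(5, 15)}
    res2 = geneset_overlap(half, other, universe)
    assert res2.table == (5, 5, 5, 5)
    with pytest.raises(ValidationError):
        geneset_overlap(set(), set(), set())


def test_top_sites_concordance_identical_fits_is_infinite(small_fits):
    _, fits, annotation, _ = small_fits
    out = top_sites_element_concordance(fits, fits, annotation, k=200)
    defined = out[out["or"].notna()]
    assert len(defined) > 0
    assert (np.isinf(defined["or"]) | (defined["n_fg"] == 0)).all()


def test_top_sites_concordance_matching_window(rng):
    """+-1 kb flank matching agrees with a brute-force interval-pair scan."""
    ann = _toy_annotation()
    pos = rng.integers(1, 7000, size=60)
    p = rng.uniform(size=60)
    fits = _fits_frame(np.full(60, 0.5), np.ones(60, dtype=int),
                       p=p, pos=pos)
    out = top_sites_element_concordance(fits, fits, ann, k=10, match_bp=1000)
    top = set(pos[np.argsort(p)[:10]])
    for cls, iv in ann.elements.items():
        expect = 0
        for _, row in iv.intervals.iterrows():
            s, e = row["start"] - 1000, row["end"] + 1000
            if any(s < pp <= e for pp in top):
                expect += 1
        got = out.set_index("label").loc[cls]
        a = got["n_fg"] if not np.isnan(got["or"]) else None
        # instances with top sites in both datasets == expect
        assert int(got["n_fg"]) == expect or np.isnan(got["or"])
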