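"""End-to-end orchestration of the synthetic study.

``run_all`` simulates a small multi-dataset study (three "tissues" drawn from
independent seed streams, the first carrying age effects), preprocesses each,
fits the robust differential model, computes the enrichment suite, aggregates
per-gene rankings across datasets, derives aging rates and group comparisons,
and computes cross-dataset concordance.  Every stage output is written as a
tab-separated table; a manifest records the config hash, seed and SHA-256
digest of each output so identical (config, seed) runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .types import Config
from .simulate import SimConfig, simulate_panel
from .preprocess import run_preprocess
from .differential import run_differential
from .enrichment import (
    directional_enrichment,
    element_enrichment,
    gene_stats,
    pathway_enrichment,
    tss_bin_enrichment,
)
from .aggregation import aggregate_gene_tables
from .aging import compare_group_rates, fit_age_model, gene_aging_rate
from .concordance import exacerbation_test, kendall_concordance, weighted_pearson
from . import io

log = logging.getLogger("methylpanel")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, meta) -> None:
    io.write_table(df.round(10), path, meta)


def run_all(
    config: Config | None = None,
    sim: SimConfig | None = None,
    outdir: str | Path = "methylpanel_run",
    seed: int | None = None,
    n_datasets: int = 3,
) -> dict:
    """Run the full synthetic study; returns the manifest dict."""
    t0 = time.time()
    config = config or Config()
    if seed is not None:
        config = Config(**{**config.resolved(), "rng_seed": seed})
    sim = sim or SimConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config": config.digest(), "seed": config.rng_seed}
    log.info("resolved config: %s", config.resolved())

    base = int(config.rng_seed) % (2**31 - 1)
    datasets = {}
    gene_tables = {}
    fit_tables = {}
    for d in range(n_datasets):
        name = f"ds{d + 1}"
        t = time.time()
        # one shared panel layout measured in every synthetic "tissue";
        # the first dataset also carries age effects for the aging stage
        cfg_d = sim.replace(seed=base + 10_000 * d, panel_seed=base,
                            frac_age_cytosines=(0.1 if d == 0 else
                                                sim.frac_age_cytosines))
        counts, sheet, annotation, truth = simulate_panel(cfg_d)
        io.write_counts(counts, outdir / f"{name}_counts.tsv", meta)
        io.write_sample_sheet(sheet, outdir / f"{name}_samples.csv", meta)
        _write(truth.to_frame(), outdir / f"{name}_truth.tsv", meta)
        if d == 0:
            io.write_annotation(annotation, outdir / "panel_genes.tsv",
                                outdir / "panel_elements.bed",
                                outdir / "panel_snp_mask.bed")
        counts, B, sheet, report = run_preprocess(counts, sheet, annotation,
                                                  config)
        _write(report.to_frame(), outdir / f"{name}_qc.tsv", meta)
        fits = run_differential(B, sheet, config)["group"]
        _write(fits, outdir / f"{name}_fits.tsv", meta)
        gs = gene_stats(fits, annotation, alpha=config.fdr_q)
        _write(gs, outdir / f"{name}_genes.tsv", meta)
        datasets[name] = (B, sheet, annotation, fits)
        gene_tables[name] = gs
        fit_tables[name] = fits
        log.info("dataset %s: %d sites, %d samples (%.1fs)", name,
                 len(fits), len(sheet), time.time() - t)

    # enrichment suite on the first dataset
    B1, sheet1, annotation1, fits1 = datasets["ds1"]
    enr = {
        "directional": pd.DataFrame(
            [directional_enrichment(fits1, config.fdr_q).as_dict()]),
        "elements": element_enrichment(fits1, annotation1, "all", config.fdr_q),
        "tss_bins": tss_bin_enrichment(fits1, annotation1, config.tss_bin_bp,
                                       alpha=config.fdr_q),
        "pathways": pathway_enrichment(fits1, annotation1, "all", config.fdr_q),
    }
    for key, df in enr.items():
        _write(df, outdir / f"enrich_{key}.tsv", meta)

    rra = aggregate_gene_tables(gene_tables)
    _write(rra, outdir / "rra_genes.tsv", meta)

    # aging analysis on the first dataset
    agefits = fit_age_model(B1, sheet1, config)
    rates_control = gene_aging_rate(agefits["age_control"], annotation1,
                                    config.fdr_q)
    rates_case = gene_aging_rate(agefits["age_case"], annotation1,
                                 config.fdr_q)
    _write(agefits["age_control"], outdir / "aging_fits_control.tsv", meta)
    _write(agefits["age_case"], outdir / "aging_fits_case.tsv", meta)
    _write(rates_control, outdir / "aging_rates_control.tsv", meta)
    _write(rates_case, outdir / "aging_rates_case.tsv", meta)
    cmp_rates = compare_group_rates(rates_control, rates_case)

    # cross-dataset concordance between the first two datasets
    ga = gene_tables["ds1"].set_index("gene_id")
    gb = gene_tables["ds2"].set_index("gene_id")
    tau, tau_p, n_tau = kendall_concordance(
        ga["p_one_sided"], gb["p_one_sided"])
    shared = sorted(set(ga.index) & set(gb.index))
    wp_r, wp_p = weighted_pearson(
        ga.loc[shared, "wmfc"].to_numpy(),
        gb.loc[shared, "wmfc"].to_numpy(),
        -np.log10(np.clip(gb.loc[shared, "p_one_sided"].to_numpy(), 1e-300, 1)),
    )
    exac = exacerbation_test(fit_tables["ds1"], fit_tables["ds2"],
                             alpha=config.fdr_q)
    concord = pd.DataFrame([{
        "kendall_tau": tau, "kendall_p": tau_p, "n_genes": n_tau,
        "weighted_pearson_r": wp_r, "weighted_pearson_p": wp_p,
        "exacerbation_or": exac.or_value, "exacerbation_p": exac.p,
        "paired_t_p": cmp_rates["paired_t_p"],
    }])
    _write(concord, outdir / "concordance.tsv", meta)

    manifest = {
        "config_hash": config.digest(),
        "seed": config.rng_seed,
        "config": config.resolved(),
        "elapsed_s": round(time.time() - t0, 2),
        "outputs": {
            p.name: _digest(p)
            for p in sorted(outdir.iterdir())
            if p.suffix in {".tsv", ".csv", ".bed"}
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("run complete in %.1fs", manifest["elapsed_s"])
    return manifest
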