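"""Run the QC chain: coverage, replicates, site filters, sample outliers.

The simulated panel includes two technical replicate pairs and one outlier
sample shifted 8 SDs in global methylation; the chain should merge the
replicates and flag the outlier on the first two principal components.
"""

from methylpanel import Config, SimConfig, run_preprocess, simulate_panel

cfg = SimConfig(seed=6, n_replicate_pairs=2, n_outlier_samples=1,
                outlier_shift_sd=8.0)
counts, sheet, annotation, truth = simulate_panel(cfg)
counts, B, sheet, report = run_preprocess(counts, sheet, annotation, Config())

print(report.to_frame().to_string(index=False))
print(f"\nplanted outlier: {truth.outlier_samples}")
print(f"excluded: {[s for s, why in report.excluded_samples]}")
print(f"retained: {counts.n_sites} sites x {counts.n_samples} samples")
# each stage's counts telescope (before - removed = after); cells below 30x
# coverage are missing, sites failing the 70% call-rate or 50% stable-call
# rules are gone, and the outlier sample is excluded by the 3-SD PCA rule
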