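"""Monte-Carlo accuracy study: how detection noise degrades registration.

Random homographies are applied to unit lattices, Gaussian detection noise
is added, the homography is re-estimated and the lattice reconstructed;
MAE and Recall@OKS>0.95 summarise the error per condition. A desk-scale
version of the published 10,000-sample sweep.
"""

from anchorreg.validation import MetricConfig, SweepConfig, run_noise_sweep

cfg = SweepConfig(
    noise_stds=(0.0, 0.02, 0.05, 0.08),
    point_counts=(4, 16),
    n_samples=400,
    seed=0,
)
result = run_noise_sweep(cfg, MetricConfig())
summary = result.summary()
print(summary[["noise_std", "point_count", "mae_mean", "recall"]]
      .to_string(index=False, float_format=lambda v: f"{v:.4f}"))
# Reading the table: at zero noise the chain is exact (MAE ~ 1e-16,
# recall 1); recall stays high through noise 0.05 and erodes beyond it,
# faster for 4 anchors (no redundancy) than for 16.
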