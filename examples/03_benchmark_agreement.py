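"""Accuracy sweep: simulate rates 15/20/25/30 bpm and measure agreement.

Runs the full estimator over a small benchmark suite and summarizes the
errors with MAE and Bland–Altman bias / 95% limits of agreement — the same
statistics used to validate non-contact vital-sign monitors against a
reference sensor.
"""

from thermorr import (assess_regions, bland_altman, extract_grid_signals,
                      generate_benchmark_suite, generate_scene)

configs, manifest = generate_benchmark_suite(
    rrs=(15.0, 20.0, 25.0, 30.0), noise_sigmas=(15.0,), n_reps=5, seed=0
)
preds, truths = [], []
for cfg, rr_true in zip(configs, manifest["rr_true_bpm"]):
    seq, box, _ = generate_scene(cfg)
    res = assess_regions(extract_grid_signals(seq, box))
    preds.append(res.rr_bpm)
    truths.append(rr_true)

stats = bland_altman(preds, truths)
print(f"scenes           : {stats.n}")
print(f"MAE              : {stats.mae:.3f} bpm")
print(f"bias             : {stats.bias:+.3f} bpm")
print(f"95% LoA          : [{stats.loa_low:+.3f}, {stats.loa_high:+.3f}] bpm")
# Sub-bpm MAE and narrow limits of agreement mean the estimator tracks the
# programmed rates; the bias shows any systematic over/under-reading.
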