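"""Why two rate estimators: spectral peak vs zero-crossing median.

On a clean breathing trace the frequency-domain rate (breath-band
periodogram peak) and the time-domain rate (median zero-crossing frequency)
agree within a couple of bpm, so the logistic gate G(5 - |RRt - RRf|) stays
near 1.  On broadband noise they disagree wildly and the gate collapses —
this disagreement is what lets the quality index reject non-respiratory
regions without knowing where the nose is.
"""

from thermorr import (SceneConfig, detrend_linear, extract_grid_signals,
                      generate_scene, periodogram, rr_from_spectrum, rr_from_time,
                      sigmoid, window_signal, zero_crossings)

seq, box, truth = generate_scene(SceneConfig(rr_true_bpm=18.0, seed=1))
traces = extract_grid_signals(seq, box)

for label, k in [("breathing cell", truth.breathing_cells[0]), ("forehead cell", 1)]:
    win = detrend_linear(window_signal(traces[k], 0.0, 15.0))
    _, rr_f = rr_from_spectrum(periodogram(win))
    rr_t = rr_from_time(zero_crossings(win))
    gate = sigmoid(5.0 - abs(rr_t - rr_f)) if rr_t is not None else 0.0
    rr_t_str = f"{rr_t:7.2f}" if rr_t is not None else "   None"
    print(f"{label:15s} roi {k:2d}: RRf {rr_f:6.2f}  RRt {rr_t_str}  gate {gate:.3f}")
print(f"\ntrue rate: {truth.rr_true_bpm} bpm")
# gate near 1 marks cross-domain agreement (respiration); near 0 marks noise.
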