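"""Inter-region pulse arrival lags and the statistical layer.

Per-region lags against the mid-forehead reference come from matched,
sub-frame-refined cardiac peaks. The region x side design (19 meta-region
pairs, 18 recordings) is then analysed with one-/two-way ANOVA, and each
area's left/right asymmetry with a mean-of-difference effect size, a BCa
bootstrap interval, and a Wilcoxon signed-rank test.
"""

import facepulse as fp

# --- lags from one synthetic recording --------------------------------------
params = fp.default_params(duration_s=22.0, seed=7, noise_sd=0.5)
frames, truth = fp.generate_video(params, frame_size=(256, 256))
analysis = fp.analyze_recording(frames, truth.landmark_set,
                                fp.AnalysisConfig(roi_size=10))
print("recovered lag vs truth (ms):")
for rid in (6, 35, 45, 90):
    if rid in analysis.lags_ms:
        print(f"  region {rid:2d}: {analysis.lags_ms[rid]:7.2f}  "
              f"(true {truth.lag_vs_reference_ms(rid):6.1f})")

# --- the repeated-recordings design -----------------------------------------
area_lags = {("forehead", "left"): -0.9, ("forehead", "right"): 6.2,
             ("nose_bridge", "left"): -5.3, ("nose_bridge", "right"): 1.0,
             ("mid_cheek", "left"): -12.3, ("mid_cheek", "right"): -13.1,
             ("nasolabial_fold", "left"): -8.1, ("nasolabial_fold", "right"): -6.8,
             ("upper_perioral", "left"): -4.3, ("upper_perioral", "right"): -4.5,
             ("chin", "left"): -0.6, ("chin", "right"): -2.2}
samples = fp.simulate_lag_samples(area_lags, n_recordings=18,
                                  between_sd_ms=10.0, seed=1)

print("\nANOVA over the region x side design:")
print(fp.anova_tables(samples).to_string(index=False,
                                         float_format=lambda v: f"{v:.4g}"))

print("\nleft/right comparison per area (mean-of-difference, 95% BCa CI):")
table = fp.area_lag_table(samples, n_boot=2000, seed=2)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\nA CI excluding zero marks a significant left/right asymmetry "
      "(forehead and nose bridge here, by construction).")
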