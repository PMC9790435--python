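"""Rainfall-decoupled trends and tree-loss anomaly recovery.

First calibrates the pixel-wise anthropogenic-trend test on burned area
that is driven purely by antecedent precipitation (the significance
rate should sit at the nominal 5%), then recovers a planted
-1 km^2/yr decoupled trend.  Finally recovers planted tree-loss anomaly
ratios from the regime x vegetation degradation summary.
"""

from fireregimes.scenarios import degradation_recovery, trend_inference

null = trend_inference(seed=1, planted_slope=0.0)
print(f"type-I error of the anthropogenic-trend flag: "
      f"{null['significant_rate']:.3f} (nominal 0.05, n={null['n_cells']})")

planted = trend_inference(seed=1, planted_slope=-1.0)
print(f"planted -1 km^2/yr trend: recovered year coefficient "
      f"{planted['mean_slope']:.2f}, t < -2 in "
      f"{100 * planted['t_below_minus2_rate']:.0f}% of pixels")

deg = degradation_recovery(seed=1)
print("\nplanted vs recovered tree-loss anomaly ratios:")
for regime, target in deg["planted"].items():
    print(f"  regime {regime}: planted {target:.1f}, "
          f"recovered {deg['recovered'][regime]:.2f}")
print(f"all-tropics baseline ratio: {deg['baseline_ratio']:.1f} (exact by construction)")
print("\nThe trend regression absorbs precipitation-driven variation, so "
      "only genuinely rainfall-decoupled change is flagged; anomaly ratios "
      "above 1 mark strata losing tree cover faster than the tropics-wide rate.")
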