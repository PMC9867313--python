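"""Turn standardized path coefficients into hierarchical indicator weights.

Group weights are the normalized second-order paths (gamma), within-group
weights the normalized loadings (lambda), and the combined weight of an
indicator is their product — so combined weights sum to 1 and feed the
fertility index directly.  Any reported coefficient set can be injected
without refitting.
"""

from semfi import compute_weights

weights = compute_weights(
    gamma={"TotalNutrients": 0.51, "AvailableNutrients": 0.60},
    loadings={
        "TotalNutrients": {"som": 0.89, "tn": 0.96, "tp": 0.46},
        "AvailableNutrients": {"an": 0.42, "ap": 0.78, "ak": 0.77},
    },
)
print(weights.to_frame().to_string(index=False))
print(f"\ncombined weights sum to {sum(weights.combined_weights.values()):.10f}")
# TN carries the largest within-group weight (0.4154) and TP the smallest
# (0.1991): total nitrogen dominates the total-nutrient signal.
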