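# semfi — SEM-weighted soil fertility indices

`semfi` builds composite **soil fertility indices (SFI)** for forest soils
the way a structural-equation modeller would: instead of assigning indicator
weights by expert judgement or principal components, it derives them from
the standardized path coefficients of a fitted latent-variable model of the
nutrient system.

It is written for forest-soil and ecosystem researchers who have (or want to
simulate) a designed soil survey — stand age groups x replicate plots x
sampling points x depth layers — measured on six nutrient indicators: soil
organic matter (SOM), total nitrogen (TN) and total phosphorus (TP) in
g·kg⁻¹, and available nitrogen (AN), available phosphorus (AP) and
available potassium (AK) in mg·kg⁻¹.

## The model

Two first-order latent factors measure the nutrient system — *total
nutrients* η₁ (SOM, TN, TP) and *available nutrients* η₂ (AN, AP, AK) —
with a second-order *soil fertility* factor ξ above them:

```
x = Λ η + δ          (measurement model)
η = Γ ξ + ζ          (structural model)
```

All latent variances are fixed to 1, so estimates are standardized paths.
The free parameters θ (loadings λ, paths γ, error variances) are estimated
by minimizing the ML discrepancy between the sample covariance S and the
model-implied covariance Σ(θ) = ΛΦΛ′ + Θ,

```
F_ML(θ) = ln|Σ(θ)| − ln|S| + tr(S Σ(θ)⁻¹) − p ,
```

with (n−1)·F_ML the model chi-square. Before fitting, the indicator battery
is screened with Cronbach's α, the KMO measure and Bartlett's sphericity
test; after fitting, CMIN/DF, CFI, TLI, IFI and SRMR are judged against the
standard reference bands, together with composite reliability
CR = (Σλ)²/((Σλ)² + Σ(1−λ²)) and average variance extracted AVE = Σλ²/k.

The fitted standardized paths become hierarchical weights by two-level
proportional normalization — β_h = γ_h/Σγ for nutrient groups,
ρ_k = λ_k/Σλ within a group, combined weight W_k = β_h·ρ_k — and each raw
indicator value x is scored on the nonlinear more-is-better curve

```
S(x) = 1 / (1 + (x/x₀)^(−2.5)),      SFI = Σ W_k · S_k ,
```

with x₀ the pooled dataset mean, so a perfectly average sample has
SFI = 0.5 and all indices live in (0, 1).

Because real surveys of this kind are rarely public, `semfi` ships a
calibrated synthetic generator: 500 cores drawn from the two-factor model
(default loadings 0.89, 0.96, 0.46 | 0.42, 0.78, 0.77, factor correlation
0.306) with realistic per-age-group means/SDs and a depth-decline profile.

## Worked example

```python
from semfi import compute_weights, score_table, summarize_sfi
from semfi.synthetic import SyntheticSpec, generate

weights = compute_weights(
    gamma={"TotalNutrients": 0.51, "AvailableNutrients": 0.60},
    loadings={
        "TotalNutrients": {"som": 0.89, "tn": 0.96, "tp": 0.46},
        "AvailableNutrients": {"an": 0.42, "ap": 0.78, "ak": 0.77},
    },
)
print(weights.to_frame()[["group", "group_weight", "indicator", "indicator_weight"]])
```

```
              group  group_weight indicator  indicator_weight
     TotalNutrients      0.459459       som          0.385281
     TotalNutrients      0.459459        tn          0.415584
     TotalNutrients      0.459459        tp          0.199134
 AvailableNutrients      0.540541        an          0.213198
 AvailableNutrients      0.540541        ap          0.395939
 AvailableNutrients      0.540541        ak          0.390863
```

TN carries the largest weight in the total-nutrient group (ρ = 0.4156) and
TP the smallest (0.1991): total nitrogen dominates the total-nutrient
signal, available nutrients outweigh totals slightly (β = 0.54 vs 0.46).
Scoring a simulated survey and summarizing by design cell:

```python
table = generate(SyntheticSpec(seed=42))
scored, x0 = score_table(table, weights)
print(summarize_sfi(scored).head(4))
```

```
age_group depth_layer   n  mean_sfi   sd_sfi
        I        0-15  25  0.524301 0.104745
        I       15-30  25  0.523239 0.088803
        I       30-45  25  0.419142 0.117672
        I       45-60  25  0.265972 0.066762
```

Mean SFI drops from ~0.52 in the topsoil to ~0.27 at 45–60 cm: the index
recovers the depth-declining fertility built into the generator, and 0.5
marks a sample exactly at the pooled indicator means.

The same chain is available from the shell:

```bash
sfi run --simulate default --seed 42 --out results/
sfi weights --gamma 0.51,0.60 --loadings 0.89,0.96,0.46:0.42,0.78,0.77
sfi indices --values 2.844,0.970,0.911,0.971,0.0536
```

`results/` then holds `reliability.csv`, `cfa_fit.csv`, `fit_indices.csv`,
`weights.csv`, `scores.csv`, `sfi_summary.csv` and a `run.log` that records
the seed and every threshold verdict; rerunning the same command reproduces
the CSVs byte for byte. The `examples/` directory contains one short script
per capability.

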