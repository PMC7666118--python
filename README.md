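# dlptp — detection of ligand–protein interactions from thermal profiles

`dlptp` analyses two-dimensional thermal proteome profiling (2D-TPP)
experiments, in which the soluble fraction of every detected protein is
quantified over a grid of *m* temperatures × *n* ligand concentrations
(one multiplexed MS run per pair of adjacent temperatures). Ligand
binding typically shifts a protein's thermal stability, so true targets
show a dose-dependent change in abundance that grows towards the
temperatures where the protein melts. `dlptp` turns this into a
statistical test with explicit false-discovery-rate control, replacing
fixed fold-change/R² cutoff rules whose error rates are unknown.

It is aimed at proteomics groups doing target deconvolution for drugs
and metabolites, and at methodologists who want a self-contained,
simulation-backed implementation to benchmark against.

## The model

For protein *i* at temperature *T_j* and log10 concentration *c_k*, two
nested models are fit to the log2 intensities *y_ijk* by bounded
least squares:

- null (no ligand effect): `y_ijk = β⁰_ij + ε`
- alternative (dose response):
  `y_ijk = β¹_ij + α_ij · δ_i / (1 + exp(−κ_i (c_k − ζ_i(T_j)))) + ε`,
  with `ζ_i(T) = ζ⁰_i + a_i T`

where `δ_i` is the maximal absolute stabilization (log2 units),
`α_ij ∈ [0,1]` the fraction realised at temperature *j*, `κ_i` a slope
shared across temperatures whose sign encodes stabilization (+) vs
destabilization (−), and the inflection `ζ_i` — the negative pEC50 —
drifts linearly with temperature. The models are compared by

`F_i = (RSS⁰ − RSS¹)/RSS¹ · d₂/d₁`, `d₁ = m_i + 4`, `d₂ = p_i − (2 m_i + 4)`,

optionally with an empirical-Bayes moderated denominator
`F̃_i = (RSS⁰ − RSS¹)/(s̃²_i d₁)`, where `s̃²_i` shrinks the residual
variance towards a prior value shared among proteins with a similar
number of observations. Because this statistic has no analytic null
distribution, it is calibrated by a bootstrap that resamples
alternative-model residuals within MS runs, adds them to the null fit,
and re-runs the full fitting/moderation pipeline; FDR is then estimated
per measurement-count stratum `γ(p) = ⌊p/10 + 1/2⌋` with a
threshold-dependent estimate of the true-null proportion π₀.

## Worked example

`python examples/01_fit_single_protein.py` simulates one spiked ligand
target (true pEC50 6.0, maximal stabilization 1.5 log2 units, noise
SD 0.05) on the standard 12 × 5 grid and fits both models:

```
observations: p = 60, temperatures: m = 12
degrees of freedom: d1 = 16, d2 = 32
RSS null = 15.7004, RSS alternative = 0.0895
F = 348.84
recovered pEC50 = 6.01 (true 6.00) at T_ref = 62.4 C
recovered max response amplitude = 1.52 log2 units (true <= 1.50)
effect size sign(kappa)*sqrt(RSS0-RSS1) = 3.95
```

The dose-response model explains almost all of the variance the
baseline model leaves (F ≈ 349), the potency estimate matches the
simulated pEC50 to 0.01 log10 units, and the positive effect size says
the protein is stabilized. The other scripts in `examples/` walk
through variance moderation, the full detection pipeline on a small
screen, the FDR-calibration benchmark, and q-q/volcano diagnostics.

A command-line interface mirrors the library:

```bash
dlptp simulate --preset ci --seed 1 -o screen.tsv --truth truth.tsv
dlptp detect --input screen.tsv --boots 20 --seed 1 -o out/
dlptp benchmark --preset ci --seed 1 -o summary.tsv
```

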