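# Methods

## Data model

A 2D-TPP screen quantifies each protein on a grid of *m* temperatures ×
*n* ligand concentrations (default geometry: 12 temperatures from 42 to
63.9 °C, 5 concentrations including a vehicle control; one multiplexed
MS run covers all concentrations at two adjacent temperatures, so
*w = m/2* runs). The canonical table is long-format with one row per
(protein, temperature, concentration) carrying the log2 intensity, the
MS-run label, and optionally the supporting peptide count. Missing
values are explicit NaNs and are excluded from every sum; they are never
imputed.

When only raw per-condition sum intensities *s* and relative fold
changes *r* are available, log2 intensities are derived as
`y_iu = log2((r_iu / Σ_l r_il) · Σ_l s_il)`. Entries supported by at
most one peptide are marked missing. Proteins keep only rows with
observed values; a protein enters the analysis when it has at least 20
non-missing measurements (on the default grid this corresponds to ≥4
temperatures × 5 concentrations; proteins that pass the count but not
that coverage are flagged in the filter report).

Concentrations are used on the log10 molar scale. The vehicle (0) has
no logarithm; it is placed `conc_offset` decades (default 2) below the
lowest tested dose, far enough down the concentration axis that it sits
on the lower asymptote of any sigmoid within the tested range while
keeping the design matrix finite. The reported potency is
pEC50 = −ζ(T_ref) where T_ref is the temperature with the largest
fitted response fraction α.

## Nested models and the F-statistic

Null model: one free baseline per observed temperature (its least
squares solution is the per-temperature mean), ν₀ = m parameters.
Alternative model: baselines plus a shared sigmoid response,
ν₁ = 2m + 4 parameters (β_j and α_j per temperature; δ, κ, ζ⁰, a
shared). Degrees of freedom for the F-test are d₁ = ν₁ − ν₀ = m + 4 and
d₂ = p − ν₁; proteins with d₂ < 1 cannot be tested and are reported
separately. The direction of the response is carried by the sign of κ
with δ canonicalized to be nonnegative, so sign(κ) > 0 means
stabilization; the signed effect size is sign(κ)·√(RSS⁰ − RSS¹).

The alternative model is fit with L-BFGS-B using an analytic gradient,
from a deterministic start: β_j at the per-temperature means, α = 0,
δ = the largest within-temperature spread, κ = the slope of a pooled
linear regression of y on log10 concentration (its sign fixes the
allowed sign of κ during the fit), ζ⁰ = the mean log10 concentration,
a = 0. Because α = 0 embeds the null model, the start already attains
RSS⁰ and monotone line searches guarantee the nesting RSS¹ ≤ RSS⁰; if
an optimizer failure ever violates it, up to 3 seeded restarts jitter
(κ, ζ⁰), and as a last resort the null solution itself is returned with
`converged = False`.

Box constraints: α ∈ [0, 1]; δ ≥ 0; |κ| ≤ 500 (per log10-concentration
unit) with its sign fixed to the initialization; ζ⁰ within the tested
concentration range ± 2 decades; |a| ≤ 1 log10 unit per °C. Convergence
tolerance is 1e-9 on the relative objective decrease with a 300
iteration cap — enough to stabilize F and pEC50 under realistic noise
while keeping a full bootstrap affordable; analyses that need
machine-precision optima (e.g. noise-free identities) can pass a
`ModelConfig` with a tighter tolerance and larger budget. δ and the
α_j are identified only through their products α_j·δ, so only the
realized amplitudes, not δ itself, should be interpreted.

## Variance moderation

The residual variance s² = RSS¹/d₂ of each protein is shrunk towards a
common value via a scaled inverse-χ² prior: 1/σ² ~ χ²_{d₀}/(d₀s₀²),
giving the posterior mean s̃² = (d₀s₀² + d₂s²)/(d₀ + d₂) and the
moderated statistic F̃ = (RSS⁰ − RSS¹)/(s̃²d₁), which reduces exactly to
F when s̃² = s². Hyperparameters are estimated per stratum by matching
the mean and variance of log s² to the log scaled-F sampling model
(s² ~ s₀²F_{d₂,d₀}) through digamma/trigamma relations, inverting the
trigamma equation for d₀ by bracketed root finding. Under-dispersed
strata yield d₀ = ∞, represented explicitly and propagating as
s̃² = s₀² with s₀² the arithmetic mean of the observed variances (the
convention of limma's squeezeVar, against which the estimator is
cross-checked in the test suite). Strata follow the same
measurement-count groups as the FDR estimation; strata with fewer than
10 proteins are merged with the nearest group before estimation.

## Bootstrap null and FDR

For each of B bootstrap rounds, every protein's alternative-model
residuals are resampled with replacement strictly within each MS run
(noise is run-specific in this design) and added to the null-model
fitted values; both models are refit on the resampled profile with the
same start-value recipe, and moderation hyperparameters are
re-estimated on each bootstrap dataset, so the null statistics reflect
the entire pipeline. Each bootstrap round draws from an independent
child seed of the user seed, making results reproducible and
checkpoint/resume safe (partial results are saved every 10 rounds).

Proteins are grouped by γ(p) = ⌊p/10 + 1/2⌋ (groups under 20 proteins
merged with their nearest neighbour). Within group g, for threshold θ:

- π̂₀g(θ) = B·#{F̃ < θ} / Σ_b #{F̃⁰ᵇ < θ}, clipped to [0, 1], with a
  zero denominator treated conservatively as 1;
- FDR̂g(θ) = π̂₀g(θ) · Σ_b #{F̃⁰ᵇ ≥ θ} / (B·#{F̃ ≥ θ}), clipped to [0, 1];

ties count as exceedances. FDR̂ is evaluated at every observed
statistic and then monotonized by sweeping thresholds from the largest
statistic downward carrying a cumulative maximum: each protein reports
the worst estimate among thresholds at least as stringent as its own
statistic. A minimum-based (q-value style) sweep is unusable here
because the threshold-dependent π̂₀ is exactly 0 at the lowest observed
statistic and the minimum would propagate that spurious 0 to every
protein; the maximum-based sweep is conservative and keeps the
per-protein FDR non-increasing in the statistic. Hits at level α are
proteins with monotonized FDR ≤ α, labelled stabilized/destabilized by
the effect-size sign.

## Synthetic benchmark

The generator emulates a screen in which most proteins ignore the
ligand. Null profiles: per-temperature baselines from a melting-curve
shape (log2 of a descending sigmoid in temperature with random midpoint
48–58 °C, slope 0.3–0.8 /°C, residual plateau 2–20%), identical across
concentrations, plus i.i.d. Gaussian noise with a protein-specific SD
drawn from a log-normal with median 0.08 log2 units and geometric SD
1.5 — the magnitude seen in real screens. Non-random missingness is
emulated by dropping the top 0/1/2 MS runs with probabilities
0.6/0.25/0.15 (exercising the γ strata) plus 2% random cell dropout.

True positives are drawn from the alternative model itself: maximal
stabilization δ ∈ [0.5, 3] log2 units (zero excluded by construction),
|κ| ∈ [2, 20], pEC50 within the tested dose range [5.3, 7.0], drift
a ∈ [−0.01, 0.01] per °C, response fraction rising sigmoidally towards
high temperatures, 80% stabilized / 20% destabilized. Defaults follow
the published study conditions where stated (5000 null profiles, 80
spike-ins, B = 100, three seeds); the `ci` preset (1000 null, 40
spike-ins, B = 20, one seed) keeps a desk-scale run of the identical
pipeline in the minutes range and is what the test suite and the
acceptance script execute.

Because the real study spiked in genuine experimental profiles whose
effect-size distribution is not published, absolute true-positive rates
are a property of these generator ranges, not a reproduction of the
original figures; what transfers is the calibration behaviour (observed
FDR at or below nominal) and the relative ordering of the methods. The
generator also omits TMT channel cross-talk, run-to-run carry-over and
correlated noise, so passing benchmarks bound what can be claimed about
real data.

The legacy comparator implements the fixed-threshold rule: per
temperature, a 3-parameter log-logistic curve (lower asymptote anchored
at the vehicle-normalized fold change 1) is fit to the fold changes; a
protein is flagged when two consecutive temperatures both reach
R² > 0.8 and at least a 1.5-fold change at the highest dose. The exact
curve parameterization of the original rule is not fully specified in
the literature; this one is documented here as the package's choice.

## Numerical choices and degenerate inputs

- RSS¹ = 0 (noise-free data) makes F infinite; such proteins are
  flagged degenerate rather than ranked.
- All-zero fold changes drop a protein with a warning; negative
  intensities or concentrations are validation errors.
- MS runs with a single residual make within-run resampling a no-op;
  this is logged, not fatal.
- π̂₀ and FDR̂ ratio estimators are clipped to [0, 1]; at finite B they
  can otherwise exceed 1.
- All randomness flows through numpy `SeedSequence` children of a
  single user seed; identical seeds give bit-identical hit tables.

## Known limitations

- The bootstrap refits both models B times per protein; at full scale
  this is cluster/overnight work (the desk-scale preset exists for
  exactly this reason).
- One shared κ and a linear ζ(T) drift are parsimonious but can misfit
  proteins whose response direction flips with temperature.
- Proteins with p ≤ 2m + 4 observations cannot be tested at all under
  this parameter counting; they are listed, not silently dropped.
- FDR estimates are per measurement-count stratum; very sparse strata
  are merged, which can blur calibration across adjacent strata.
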