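# Methods

This note documents the models, the numerical choices, what the synthetic
generators do and do not emulate, and the known limitations of the package.

## Binding isotherm with ligand depletion

MST titrations here vary the membrane-protein concentration against a fixed
concentration of fluorescent partner (P_tot, default 17 μM). At
dissociation constants of tens of μM and titrant concentrations of
0.4–160 μM, binding measurably depletes the free titrant, so the model
composes the exact 1:1 mass-balance root

L_free = ½(L_tot − P_tot − K_d) + √(¼(K_d + P_tot − L_tot)² + L_tot K_d)

with the hyperbolic signal y = S1 + (S2 − S1)·L_free/(L_free + K_d). The
implementation clamps tiny negative round-off at stoichiometric depletion
(K_d → 0, L_tot ≤ P_tot) to zero.

Fitting is trust-region least squares over (S1, S2, log10 K_d) with K_d
bounded in [10⁻³, 10⁵] μM. The log parameterization and five log-spaced K_d
starts address the flat likelihood when K_d greatly exceeds the largest
concentration — a single start from the wrong side of the data range stalls
on that plateau. S1/S2 start from the low- and high-concentration signal
means. Standard errors come from the Jacobian covariance at the optimum
(the K_d SE by the delta method from log10 K_d). Replicates are pooled into
one global fit by default, mirroring how triplicate dilution series are
usually plotted and fitted as one curve; per-replicate fits are available
via `pool_replicates=False`.

**No-binding rule.** A series is declared non-binding when the
three-parameter isotherm fails to beat the constant model in an
extra-sum-of-squares F-test at α = 0.05, or when the fitted K_d lands on
its upper bound. This flags flat control series (chelated Ca²⁺, inhibitor
block, binding-deficient mutants) without thresholding on signal amplitude,
which would depend on the (arbitrary) signal units.

**Fnorm.** Raw MST traces reduce to Fnorm = mean(F0 window)/mean(F1
window). The automatic F1 choice slides a fixed-width window (default 1 s)
over the post-heating region and maximizes |ΔF|/pooled SD — the
signal-to-noise criterion instrument software uses — with ties broken by the
earliest window. Because S1 and S2 are free, fits are indifferent to Fnorm
vs ΔFnorm offset conventions and to affine rescaling of the signal axis.

## Dose response

y = A1 + (A2 − A1)/(1 + 10^((x0 − x)p)) on x = log10(concentration), with
IC50 reported as 10^x0. Fits multi-start over three midpoints × three Hill
slopes; a curve indistinguishable from constant (A1 ≈ A2, or F-test
failure) is returned unconverged rather than with an arbitrary midpoint.
A note on precision: for a 12-point two-fold series fitted with all four
parameters free at 2% noise, the Fisher information gives an IC50 sampling
SD near 12% — single experiments at this design localize the log-midpoint
x0 well but the linear-scale IC50 only coarsely. Recovery tests therefore
check the median over repeated experiments (bias), plus x0 for single
experiments.

## Stopped-flow shrinkage and permeability conversions

Shrinkage traces rise as an encapsulated self-quenching fluorophore
dequenches during osmotic water efflux. They are fitted with
baseline + a_f(1 − e^(−k_f t)) + a_s(1 − e^(−k_s t)) (signed amplitudes, so
falling quench-style traces fit identically). Rates are fitted in log space
with three start pairs spanning the trace duration. The faster rate is
selected for permeability: the slow component tracks protein-free liposomes
and is insensitive to reconstitution efficiency. Degenerate fits (rate
ratio < 1.5, or either amplitude < 1% of the total) fall back to a single
exponential and are flagged, so that protein-free preparations do not
yield a spurious fast component.

P_f = k/((S/V₀)·V_w·C_out) with V_w = 18 cm³ mol⁻¹ and C_out in mol cm⁻³
(0.1 Osm default). The default geometry is a 100-nm-extrusion sphere:
r = 50 nm, S/V₀ = 3/r = 6×10⁵ cm⁻¹, making the denominator exactly 1080 and
P_f = k/1080 cm/s.

**Channel density and P_u.** SuD = 1/(area per channel), where
area = lipids-per-channel × A_m / leaflets, A_m = 0.47 nm², two leaflets.
The lipid-to-protein ratio is interpreted on a mass basis by default
(reconstitution protocols typically quote mass LPR; molecular weights are
then required) with a molar option; `oligomer` selects per-monomer (default)
or per-tetramer accounting. All four conventions are exposed because the
published values in this field do not always state them, and they differ by
factors of a few. P_u = (P_f − P_f,control)/SuD subtracts the bare-bilayer
control permeability by default so that P_u reflects channel-mediated flux
only; a control exceeding the sample clamps P_u to zero with a warning.

## Calcein quench and volume conversion

Cell traces are a 5-s baseline read followed by injection of the osmotic
challenge (75 μL of 400 mM mannitol into 75 μL of medium → 200 mM, a
200 mOsm gradient) and a 50-s decay read. The post-injection segment is
fitted with F_inf + (F0 − F_inf)e^(−kt); the injection time is configured
(default 5 s) or detected as the maximum-|derivative| sample. The same
constant-model F-test as above flags traces with no resolvable decay
(k = 0). Rate constants are reported raw and, when a monotone
fluorescence→volume standard curve is supplied, after volume conversion;
the calibration must pass through (1, 1) and values outside its range are
flagged as extrapolation.

## Accumulation kinetics

Normalized surface-abundance time courses are fitted with 1 − e^(−kt)
(plateau fixed at 1 by the normalization), t½ = ln 2/k. Fits whose plateau
is less than half-reached at the last time point are flagged non-saturating.

## Tissue and imaging metrics

Water content (%) = (wet − dry)/wet × 100, rejecting dry ≥ wet.
Perivascular enrichment uses strictly hierarchical averaging: per image,
mean of peri-endothelial ROI means over mean of non-peri means
(mean-of-means weights ROIs equally, rather than pooling pixels); per
animal, the mean of its image ratios; per group, statistics over animal
values, so animals with more images carry no extra weight. Positive-pixel
counting thresholds at the maximum pixel value over antibody-control images
— the smallest threshold at which every control counts zero — and counts
strictly greater values. CAP amplitude is trough-to-next-peak after the
stimulus artifact, with extrema required to have prominence ≥ 5% of the
trace range (a smoothing-free noise guard); CAP area is the trapezoidal
integral of the full-wave-rectified negative component.

## Synthetic data: what it does and does not emulate

Generators reproduce the experimental designs — 12–16-point titrations at
0.4–160 μM against 17 μM partner, two-fold inhibitor dilutions, 2-s
stopped-flow traces averaged over 10 readings (dt = 2 ms), 5 + 50 s quench
reads at 50-ms sampling, wet weights around 0.1 g, 4–9 images per animal
with 3–10 ROIs per image on a 0–255 intensity range — with additive
Gaussian noise on fluorescence-derived signals and unit-mean lognormal
noise on weights and intensities (which must stay positive). Seeds are
mandatory arguments.

They do not emulate instrument-level artifacts: MST thermograms and
photobleaching, stopped-flow mixing dead time and light-scattering drifts,
plate-reader injection transients, dye leakage, image shading or
segmentation error, or between-day batch effects. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
designs and noise models, not robustness to those artifacts.

## Numerical choices and degenerate inputs

All optimizers use scipy trust-region least squares with xtol = ftol =
10⁻¹², multi-start, and rates/K_d in log space. Ties in the Fnorm window
search go to the earliest window. Kruskal–Wallis uses mid-ranks with the
tie-corrected H; for total n ≤ 8 the permutation null is enumerated exactly
(multinomial assignments), otherwise the χ² approximation with k − 1 df is
used. Conover–Iman uses the pooled rank variance
S² = (ΣR² − N(N+1)²/4)/(N−1), scale S²(N−1−H)/(N−k) and N − k df; pairs with
a singleton group are flagged untestable. The binding-constant Z-test
defaults to one-sided (directional) reporting with a two-sided option; both
conventions are recorded in the result. Bonferroni adjustment is
min(1, m·p); the accompanying one-way ANOVA is reported but does not gate
the pairwise tests unless requested.

## Limitations

- The binding model is strictly 1:1; cooperative or two-site binding is out
  of scope, as are fluorescence-attenuation corrections at high inhibitor
  concentrations.
- Shrinkage kinetics use exponential fits, not a full osmotic volume-flux
  ODE; P_f is therefore an initial-rate-style estimate tied to the assumed
  sphere geometry.
- Published single-channel permeabilities depend on SuD conventions that
  are often unstated; this package exposes the conventions rather than
  asserting any one literature value.
- Group summaries assume animals (not repeated measures) are the
  independent unit; mixed-model time-course analysis is out of scope.
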