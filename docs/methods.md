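# Methods

## Physical model

The package analyses ligand-induced quenching of the intrinsic (tryptophan)
fluorescence of a protein held at fixed concentration P while the total
ligand concentration C_Q is stepped up.  Two mechanisms are distinguished:

- **Static quenching**: the ligand forms a non-fluorescent ground-state
  complex.  With 1:1 stoichiometry and the *free-ligand approximation*
  (free ≈ total ligand, valid when the ligand is in excess over protein),
  the emitted intensity is proportional to the unbound protein fraction,
  F = F₀/(1 + K·C_Q), which makes the Stern–Volmer plot F₀/F vs C_Q exactly
  linear with slope K.  The apparent constant *decreases* with temperature
  (the complex dissociates), and the formal bimolecular rate constant
  K_q = K_SV/τ₀ exceeds the diffusion-limited ceiling.
- **Dynamic (collisional) quenching**: F₀/F = 1 + K_SV(T)·C_Q with K_SV
  *increasing* in temperature and K_q at or below ≈ 2×10¹⁰ M⁻¹s⁻¹.

The mechanism call requires both pieces of evidence (temperature trend of
K_SV and the K_q ceiling) to agree; anything else returns ``indeterminate``
with the evidence attached rather than a guess.

## Fits and their numerics

All four linearizations are unweighted ordinary least squares on the
transformed variables, which mirrors universal practice for these plots.
The reciprocal and log transforms make the errors heteroscedastic; this is
documented, not corrected, because the reported quantities are defined by
the conventional unweighted fits.

- **Stern–Volmer**: by default the intercept is fixed at its theoretical
  value 1 (the form in which K_SV tables are reported); a free-intercept mode
  is available and its deviation from 1 serves as a data-quality diagnostic.
  R² is reported as the squared Pearson correlation of (C_Q, F₀/F) in both
  modes.
- **Lineweaver–Burk**: slope 1/(K_LB·F₀) and intercept 1/F₀ of
  1/(F₀−F) vs 1/C_Q; K_LB = intercept/slope with its standard error from the
  delta method using the full slope–intercept covariance.  The fit refuses
  points with F ≥ F₀ (the reciprocal is undefined; such points signal no
  quenching or noise dominance) and rejects non-positive fitted slope or
  intercept as inconsistent with the quenching model.  On ideal static data
  the Stern–Volmer and Lineweaver–Burk constants coincide algebraically.
- **Double-log binding fit**: slope n (binding sites), intercept log₁₀K.
  se(K) = ln(10)·K·se(intercept).  Base-10 logs here, natural logs in the
  van't Hoff fit.
- **van't Hoff**: ln K vs 1/T with R = 8.314 J·mol⁻¹·K⁻¹; ΔH⁰ = −R·slope
  (reported in kJ·mol⁻¹), ΔS⁰ = R·intercept (J·mol⁻¹·K⁻¹); no heat-capacity
  term.  ΔG⁰(T) = ΔH⁰ − TΔS⁰, with −RT·ln K available as a consistency
  route.  Mixed kJ/J units follow the field's reporting convention; the
  conversion lives in one place.
- Two-point regressions are computed in closed form with zero parameter
  covariance (they interpolate exactly).

**Intercept leverage — the key precision fact.**  The double-log intercept is
read at C_Q = 1 M while the data sit at 10⁻5.5–10⁻4.5 M, i.e. the intercept
is extrapolated ≈ 5 decades beyond the data.  Any slope noise is therefore
amplified ~5× into log₁₀K.  At the standard design (five concentrations
3.5–35 µM, K ≈ 2.9×10⁴ M⁻¹) with 1% multiplicative intensity noise, a single
fit has σ(log₁₀K) ≈ 0.26 even though n is recovered to ±0.06.  The estimator
is median-unbiased (measured −0.3% over 5000 replicates), but medians over a
few hundred titrations still wander by several percent.  Consequences
adopted throughout: per-temperature constants intended for downstream use
(especially the van't Hoff regression, whose whole signal is Δln K ≈ 0.05
across 288–309 K) are medians over thousands of simulated replicates in the
reproduction script; K_SV, which has no extrapolation leverage, is the
precise quantity and anchors the site-marker ratio checks.

## Binding forces

The sign pattern of (ΔH⁰, ΔS⁰) maps to the dominant interaction:
(+,+) hydrophobic; (−,−) hydrogen bonding and/or van der Waals;
(−,+) electrostatic (ΔH⁰ = 0 with ΔS⁰ > 0 is included here — the classic
near-zero-enthalpy electrostatic signature).  The (+,−) quadrant has no
standard assignment and returns an explicit ``indeterminate``.  In an
electrostatic call, |ΔH⁰| ≥ 4 kJ·mol⁻¹ (configurable) raises a caveat flag:
an enthalpy that far from zero suggests hydrogen bonding contributes too.

## Inner-filter correction

F꜀ₒᵣᵣ = F_obs·10^((A_ex+A_em)/2) with decadic absorbances ("antilog" is read
base-10, as absorbance is decadic).  The correction depends on the
absorbances only through their sum, its factor is ≥ 1, and it is strictly
increasing in each argument.  A series is corrected exactly once — the
``corrected`` flag makes double application an error, and every fit refuses
an uncorrected series unless explicitly overridden — because silent double
correction is a real analysis bug.  Per-point absorbances are expected; a
single measured pair may be broadcast across a manifest when absorbances
were taken at one representative concentration.  UV-Vis difference spectra
(complex minus ligand) are pointwise; mismatched grids require an explicit
interpolation flag and are resampled with a cubic spline (error ≪ 1e-6 for
smooth bands on nm-scale grids); negative differences are preserved.

## Conformational probes

Synchronous-scan peak positions use argmax with 3-point parabolic
refinement (±0.05 nm on nm-sampled Gaussian bands); a shift above 2 nm
(≈ slit-limited resolution; no numeric criterion is standard) is called
significant.  Pure multiplicative quenching of a fixed band shape always
yields zero shift.  EEM peak picking masks the Rayleigh line (λ_em = λ_ex)
and its first harmonic (λ_em = 2λ_ex) to ±10 nm, dilates the mask by one
grid node so that points which are maxima only because a neighbour was
masked are not reported, applies a 5%-of-maximum intensity floor, and
resolves remaining candidates by greedy non-maximum suppression at 20 nm in
both axes.  Percent quench is read at the *reference* peak coordinates (no
re-search), matching the convention of reporting intensity drops at fixed
positions when no peak shift occurs; it is invariant under common rescaling
of both matrices.

## Site-marker competition

Both series (ligand titration of free protein, and of protein
pre-equilibrated 1:1 with a site marker) are fitted identically; the
displacement call is ratio_K = K_marker/K_free < 0.5 (a ≥ 2-fold drop,
configurable) — the literature criterion is only a qualitative "significant
diminution", so a two-fold reduction is the operational threshold.  Both the
K and K_SV ratios are reported; the call uses K, but K_SV is the far more
precise ratio (see the leverage note above).

## Synthetic data generator

The generator emulates the standard study design: protein 1.5 µM, five
ligand aliquots 3.5–35 µM (final cuvette concentrations), temperatures
288/298/309 K, excitation 280 nm, Gaussian emission band centred at 340 nm
(width 25 nm) read at its maximum, τ₀ = 2.7 ns.  Ground truth is either a
fixed K or a (ΔH⁰, ΔS⁰) pair expanded through the van't Hoff relation;
supplying both with several temperatures is rejected as ambiguous.

- *Fluorescence model*: non-fluorescent 1:1 complex (a
  ``complex_fluorescence_fraction`` can relax this); ligand native
  fluorescence defaults to zero, with an optional additive band for
  stress-testing F extraction.
- *Ligand depletion*: optional exact 1:1 equilibrium via the quadratic
  solve on total concentrations.  Because free < total ligand, the observed
  quench ratio then sits below the ideal line pointwise and the
  forced-intercept Stern–Volmer slope underestimates K one-sidedly.  (The
  double-log intercept is *not* one-sided under depletion: the tilted slope
  pivots the 5-decade extrapolation and can overshoot K.)
- *Inner filter*: absorbances linear in C_Q (Beer's law; defaults
  ε_ex = 3500, ε_em = 250 M⁻¹cm⁻¹, 1 cm path — realistic magnitudes for a
  purine antiviral at 280/340 nm, giving A_ex ≤ 0.12 at the top
  concentration).  The attenuation is the exact inverse of the correction,
  so the correction recovers the true intensities to machine precision.
  Note the *direction* of the uncorrected bias: attenuation grows with C_Q,
  so skipping the correction inflates the apparent quenching and biases K
  high.
- *Noise*: multiplicative Gaussian on every recorded intensity (shot-noise
  like at high signal), default sd 1% where a noisy study is simulated.
  One integer seed drives all draws; replicate indices offset the stream
  deterministically, so outputs are bit-reproducible.

What the generator does **not** emulate: photobleaching, drift, Raman
scatter, pH effects, ligand self-association, multi-site heterogeneity, or
instrument-specific baselines.  Passing round-trip tests therefore
demonstrates correctness of the analysis chain under the model's own
assumptions — not robustness to every artefact of real spectra.

## Pipeline and reproducibility

`run_pipeline` executes correction → quenching fits → mechanism → binding
fits → van't Hoff → forces → (optional) EEM and competition stages from a
YAML study manifest; stages lacking inputs are skipped with a logged reason,
never fabricated, and any stage error aborts naming the stage and offending
input.  Report tables print with the field's display conventions (K in 10⁴
M⁻¹, K_q in 10¹³ M⁻¹s⁻¹, energies to 2 decimals) while a JSON companion
retains full precision; identical manifests produce byte-identical reports.
The reproduction script (`scripts/acceptance.py`) reports per-temperature
constants as medians over 2000 replicate titrations (101 replicate pairs for
the competition ratio) — the sizes at which the van't Hoff enthalpy sign and
the displacement call are stable, per the precision analysis above.
Replicates whose double-reciprocal intercept comes out non-positive, or
whose weakly-quenched marker points fluctuate above F₀, are dropped from the
affected median only, as a re-measured determination would be.

## Known limitations

- The free-ligand approximation is baked into the reproduction path (no
  depletion correction), matching the conventional analysis; the exact
  equilibrium exists only in the generator for bias studies.
- No global or nonlinear fitting (combined static+dynamic models,
  Clarke–Glew), no PARAFAC for EEMs, no vendor binary formats.
- The Lineweaver–Burk and double-log transforms are noise-amplifying by
  construction; reported standard errors describe the transformed-space fit
  and inherit that amplification.
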