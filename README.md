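# quenchbind

Fluorescence-quenching analysis of protein–ligand binding, built for the
standard drug–serum-albumin workflow: a single-tryptophan protein (e.g. human
serum albumin, HSA) is titrated with a ligand, the tryptophan emission is
progressively quenched, and the quench curve is turned into binding constants,
thermodynamics, and binding-site assignments.

`quenchbind` covers the whole chain from raw titration spectra to report
tables:

- **Inner-filter correction** — F꜀ₒᵣᵣ = F_obs · 10^((A_ex + A_em)/2), undoing
  attenuation of the excitation/emission beams by the absorbing ligand.
- **Stern–Volmer fit** — F₀/F = 1 + K_SV·C_Q, plus the bimolecular quenching
  rate constant K_q = K_SV/τ₀ (default τ₀ = 2.7 ns) and a static/dynamic
  mechanism call from the temperature trend of K_SV and the diffusion ceiling
  K_q ≈ 2×10¹⁰ M⁻¹s⁻¹.
- **Lineweaver–Burk (double-reciprocal) fit** — 1/(F₀−F) = 1/F₀ + 1/(K_LB·F₀·C_Q).
- **Double-log binding fit** — log₁₀((F₀−F)/F) = log₁₀K + n·log₁₀C_Q, giving
  the binding constant K and the number of binding sites n.
- **van't Hoff thermodynamics** — ln K = −ΔH⁰/(RT) + ΔS⁰/R, then
  ΔG⁰ = ΔH⁰ − TΔS⁰, and a binding-force classification from the signs of
  (ΔH⁰, ΔS⁰): (+,+) hydrophobic, (−,−) H-bond/van der Waals, (−,+) electrostatic.
- **Conformational probes** — peak-shift detection in synchronous scans
  (Δλ = 15 nm → Tyr, 60 nm → Trp) and excitation–emission-matrix (EEM) peak
  picking with Rayleigh-scatter masking and percent-quench tables.
- **Site-marker competition** — paired fits with/without warfarin or ibuprofen
  (Sudlow site I/II probes) and a displacement call on the K ratio.
- **A forward simulator** — 1:1 static-quenching titrations (non-fluorescent
  complex), with van't Hoff temperature dependence, inner-filter attenuation,
  optional ligand depletion, and seeded multiplicative noise, so every stage
  of the pipeline can be exercised and validated without instrument data.

The linearized fits are exposed both as scikit-learn-style estimators
(`SternVolmerRegressor`, `LineweaverBurkRegressor`, `DoubleLogRegressor`,
`VantHoffRegressor` — `fit`/`predict`, `get_params`, fitted attributes with
trailing underscores) and as series-level functions (`fit_stern_volmer`,
`fit_double_log`, `fit_vant_hoff`, ...) that operate on `TitrationSeries`
objects loaded from plain-text manifests.

## Worked example

Simulate a noiseless three-temperature study (ground truth
ΔH⁰ = −1.79 kJ·mol⁻¹, ΔS⁰ = 79.40 J·mol⁻¹·K⁻¹, 1.5 µM protein, ligand
3.5–35 µM, inner-filter attenuation on) and run the full pipeline:

```bash
quenchbind simulate --out-dir demo --seed 42 --noise 0.0
quenchbind run --manifest demo/study.yaml
```

which prints

```
== quenching/binding ==
T_K	K_SV_1e4	K_SV_se_1e4	K_q_1e13	R2_SV	K_LB_1e4	R2_LB	K_1e4	n	R2_bind
288.0	2.97	0.0	1.1	1.0	2.97	1.0	2.97	1.0	1.0
298.0	2.89	0.0	1.07	1.0	2.89	1.0	2.89	1.0	1.0
309.0	2.82	0.0	1.04	1.0	2.82	1.0	2.82	1.0	1.0
mechanism: static
== thermodynamics ==
T_K	dG0_kJ	dH0_kJ	dS0_J	R2
288.0	-24.66	-1.79	79.4	1.0
298.0	-25.45	-1.79	79.4	1.0
309.0	-26.32	-1.79	79.4	1.0
binding forces: electrostatic
```

Reading the output: the Stern–Volmer constant K_SV ≈ 2.9×10⁴ M⁻¹ *decreases*
as temperature rises and K_q ≈ 10¹³ M⁻¹s⁻¹ sits far above the diffusion
ceiling, so quenching proceeds through a ground-state complex (static).  The
double-log fit recovers n = 1.00 (one binding site) and K per temperature; the
van't Hoff regression on those K values returns exactly the generating
ΔH⁰/ΔS⁰, the per-temperature ΔG⁰ < 0 (spontaneous binding), and the
(−ΔH⁰, +ΔS⁰) sign pattern classifies the driving force as electrostatic.
With measurement noise enabled (`--noise 0.01`), individual double-log K
values scatter widely because the intercept is extrapolated ~5 decades beyond
the micromolar data — see `docs/methods.md` for the precision analysis.

The same stages are available programmatically:

```python
import quenchbind as qb

cfg = qb.SynthConfig(dH0_true_kJ=-1.79, dS0_true_J=79.40, inner_filter=True)
series = qb.apply_correction(qb.generate_titration(cfg, 298.0))
print(qb.fit_stern_volmer(series).K_sv)   # 28930.1...
print(qb.fit_double_log(series).n)        # 1.0000...
```

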