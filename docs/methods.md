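# Methods

## Physical model and units

Positions are in Å and charges in elementary charge e. Potentials and
fields are kept in the native units of the bare Coulomb sum (e/Å, e/Å²);
the single conversion constant K_COUL = 332.0636 kcal·mol⁻¹·Å·e⁻² is
applied once, at the energy level. This keeps every intermediate number
auditable against the raw sum over charges. ε_eff is a dimensionless
divisor, default 1.0 (explicit-solvent convention). The field sign is
physical: positive field points from C toward O, i.e. φ(C) > φ(O).

A hard singularity guard rejects any environment charge closer than 0.5 Å
to an evaluation point: fields are only ever evaluated at probe-atom
centres, which real scenes keep clear, so a violation indicates a
malformed input rather than physics. No distance cutoff is applied by
default (the potential sum runs over all charges); an optional cutoff
radius reproduces the finite electrostatic cutoff of typical MD setups.

## The two interaction-energy schemes

1. **Point-charge scheme.** The probe carries charges q_C, q_O and the
   energy is K_COUL (q_C φ_C + q_O φ_O). With the linear polarizable-probe
   model q_O = αF + q0, q_C = −q_O, the energy of the probe in a uniform
   field is −K_COUL (αF + q0) F l: an exact quadratic in F, even when
   q0 = 0, with extremum at F = −q0/(2α). We implement the bare
   interaction form without the ½ self-polarization work term; published
   presentations of the quadratic relation do not state the sign or the
   ½ convention, and only evenness and the extremum location are
   quantitative claims. The sign adopted (stabilizing, negative for α > 0)
   is the one that falls out of the point-charge energy itself.

2. **Embedded-QM scheme.** Per frame and method, E_EI = E_total − E_self,
   where E_total is the probe energy embedded in the environment charges
   and E_self the gas-phase energy at the identical geometry. E_EI is
   always recomputed from the two columns, never trusted from a file; the
   operation is exactly linear and gauge-invariant.

## Segmented fit and equivalent atomic charges

Samples are partitioned by field sign; each segment gets an independent
free-intercept OLS fit. Free intercepts rather than forcing the lines
through the origin: the constant-dipole model implies zero intercepts, so
the fitted intercepts act as a diagnostic (they should be ≈ 0) while the
EAC is derived from the slope only, q = −k/(K_COUL l). Samples with field
exactly 0 are excluded from both segments and counted — a deterministic
rule for a measure-zero event. R² per segment is computed from sums of
squares (1 − SS_res/SS_tot), with the zero-variance noiseless edge case
mapped to 1 when the residuals are zero; `scipy.stats.linregress` returns
NaN there.

The bond length enters the EAC as the fixed constant 1.14 Å by default; an
option substitutes per-frame bond lengths during correction. A
nonparametric bootstrap (default 1000 resamples, seeded) attaches a
percentile CI to |k1|/|k2|; resampling is stratified by field sign so
every resample keeps both segments populated (an unstratified resample can
empty a thin segment, and the stratification leaves the per-segment OLS
distributions unchanged).

The central internal identity: for noiseless samples generated from any
piecewise EAC model, the fitted unsigned slope ratio equals
|q_pos|/|q_neg| exactly. This is what makes the published slope ratios
(0.83, 1.80, 3.02) and the published charge pairs mutually consistent, and
it is what `scripts/acceptance.py` recomputes.

## Correction and agreement

E_corrected = E_low − E_EAC(low, F) + E_EAC(high, F), per frame. When the
two models coincide the input is returned unchanged (exact identity, no
float round-trip). Agreement is scored as squared Pearson correlation plus
MUE; R² alone is invariant to affine maps including sign flips, so MUE is
always reported alongside. Whether published R² values are
Pearson-squared or regression-R²-against-identity is not stated anywhere
we can check; Pearson-squared is implemented and MUE is the stricter
companion.

## Bond-length detrending

The weak coupling of energies and charges to the CO bond-length
fluctuation is removed, optionally (default off), by OLS on the centered
bond length: residuals keep the series mean and are exactly uncorrelated
with the regressor, and the fitted slope is logged. How the original
analysis "eliminated" this influence is unstated; centered-OLS removal as
a pre-pass is the simplest reproducible reading.

## Synthetic generator (the stated world)

The generator emulates the *statistical structure* of QM/MM MD output —
not CO dynamics, heme chemistry, or water structure. A green test
therefore establishes that the analysis machinery is correct on data with
the right structure, not that any simulation result is reproduced.

Defaults, chosen once:

- **Field distribution**: symmetric two-sided, |N(0, 0.01 e/Å²)| with a
  random sign (asymmetry knob available). The absolute field scale is
  never published for this system; 0.01 e/Å² ≈ 0.5 V/Å is a realistic
  protein-interior scale and makes ~±1 kcal/mol probe energies with
  ~0.1–0.25 e charges.
- **Energy noise**: σ = 0.1 kcal/mol Gaussian — a calibration choice that
  places corrected-vs-target MUE near the 0.1 kcal/mol scale reported for
  real trajectories; not a fit.
- **ESP response**: α = 5.0 e/(e/Å²), q0 = 0.005 e (O charges ~±0.1 e at
  typical fields; small gas-phase charge).
- **Bond length**: N(1.14, 0.02) Å; bond-length energy coupling
  0.3 kcal/mol/Å.
- **Angle mixture**: B1:B2 weights 3.45:1 at means 115°/52.5°
  (52.5° splits the 50°/55° values cited for the acute mode), normal
  components truncated to [0, 180] by rejection. The spread, 8°, is
  constrained by the generator's contract that classified state counts
  recover the mixture weights within binomial sampling error at
  n = 10,000: at spreads ≳10° the 115° component leaks across the 90°
  boundary at the percent level and biases the classified ratio by more
  than 3 standard errors. Only mode locations are published; the spread is
  our choice and 8° keeps leakage (~0.09%) negligible.
- **Scenes**: probe along x, Fe at 3–5 Å in a random direction,
  charges uniform in a 3–25 Å shell (volume-uniform radii), N(0, 0.4 e)
  magnitudes with a final balancing charge for net neutrality. Fields
  recorded for scenes are always recomputed microscopically from the
  charges.

Every generator output is a pure function of (spec/truth, seed).

## B-state classification

The Fe···C≡O angle is the arccos of the normalized dot product at C.
Frames with angle > 90° are B1, ≤ 90° B2; the modes sit at ~115° and
~50–55°, so the boundary rule cannot move populations, and the
deterministic tie-break (90° → B2) exists for testability. Angles are
counted per saved frame with no smoothing or reweighting. Histograms use
half-open bins (last bin closed) over [0, 180] with a width that divides
180 evenly (default 2°).

## Pipeline determinism

All tables are CSV with 10-significant-digit floats. In generator mode the
pipeline writes its tables and then *reads them back* before fitting, so
the composed pipeline is bit-for-bit identical to running the standalone
CLI stages on the same files. Outputs are stamped with the seed and a hash
of the scientific configuration (the output directory is excluded from the
hash). Stage failures abort with the stage name and remove partial
outputs.

## Known limitations

- No Ewald/periodic electrostatics; plain Coulomb sums only.
- The probe's polarization is a single linear charge response; no
  polarizable force field, no multipoles beyond the piecewise dipole.
- Published slope ratios can be checked only as ratios: the absolute
  slopes depend on the unpublished field scale.
- The nanosecond QM/MM MD B1/B2 ratios (1.09/1.54/3.45) require a QM
  engine and are not desk-reproducible; the package verifies the internal
  consistency between the slope-ratio statistic and the B-state machinery
  instead.
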