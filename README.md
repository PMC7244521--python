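# costark

Analysis toolkit for the electrostatics of a diatomic CO probe in a charged
protein environment — the vibrational-Stark-style statistics behind the two
orientational "B states" of photodissociated CO in the myoglobin docking
site, and an equivalent-atomic-charge (EAC) scheme for correcting
mean-field QM/MM interaction energies toward a correlated target.

## Who this is for

Groups running QM/MM trajectories of small probes (CO, CN⁻, carbonyls) in
proteins who want, without any QM engine in the loop:

- electric fields along the probe bond from point charges,
- interaction-energy extraction from embedded/gas-phase energy tables,
- the sign-segmented field–energy regression and its k1/k2 statistic,
- EAC dipole models, correlation-style energy correction, and
- Fe···C≡O angle / B1–B2 population analysis,

plus a synthetic generator that emulates all of these inputs for testing.

## The model

The potential at the probe atom centres is a bare Coulomb sum over the
environment point charges, φ(r) = (1/ε_eff) Σ_j q_j / |r − r_j| (ε_eff = 1
with explicit solvent), and the mean field along the bond is

    F = (φ(r_C) − φ(r_O)) / |r_CO|        [e/Å², positive from C toward O]

The QM/MM interaction energy E_EI = E_total − E_self is, statistically,
linear in F with a different slope on each field sign: OLS on the two
segments gives slopes k1 (F > 0) and k2 (F < 0), whose unsigned ratio
|k1|/|k2| tracks the B1/B2 population ratio. Each slope maps onto a
constant-moment dipole, E = μ·F with μ = q·l (l = 1.14 Å), so that

    q = −k / (K_COUL · l)                 [K_COUL = 332.0636 kcal·mol⁻¹·Å·e⁻²]

is the equivalent atomic charge of the O atom (q_pos > 0 under positive
fields, the C⁻O⁺ state; q_neg < 0 under negative fields). Replacing a
low-level method's EAC energies with a high-level method's, frame by frame,

    E_corrected = E_low − E_EAC(low, F) + E_EAC(high, F)

corrects the low-level interaction energies toward the high-level target;
agreement is scored with Pearson R² and the mean unsigned error (MUE).

## Worked example

```python
import numpy as np
from costark import SegmentedStarkModel, GeneratorTruth, generate_field_energy_table

rng = np.random.default_rng(0)
truth = GeneratorTruth()                       # MP2-like EAC truth, σ = 0.1 kcal/mol
field_df, energy_df = generate_field_energy_table(truth, 10_000, rng)
sub = energy_df[energy_df["method"] == "MP2"]
e_ei = (sub["E_total"] - sub["E_self"]).to_numpy()
res = SegmentedStarkModel(field_df["field"].to_numpy(), e_ei,
                          method_label="MP2").fit(n_boot=1000, seed=0)
print(res.summary())
```

prints

```
Segmented field-energy fit [MP2]
==========================================================
segment           n         slope   intercept       R2
field > 0      4934      -96.3067      0.0016   0.9705
field < 0      5066       32.2094      0.0019   0.7892
----------------------------------------------------------
|k1|/|k2| = 2.9900   (95% bootstrap CI [2.9437, 3.0401], B=1000)
EAC (l = 1.14 A): q_pos = +0.2544 e, q_neg = -0.0851 e
```

The positive-field slope is ~3× the negative-field one: the C⁻O⁺
orientation couples to the field three times more strongly than C⁺O⁻,
and the recovered equivalent charges (+0.2544/−0.0851 e) match the
generating truth (+0.2541/−0.0843 e) within the bootstrap uncertainty.

A full study — tables, fits, correction, B-state counts — runs from the
shell:

```
costark simulate --n-frames 10000 --seed 1 --outdir study
costark decompose study/energies.csv --out study/ei.csv
costark fit-eac study/fields.csv study/energies.csv --out study/fits.json
costark classify study/angles.csv
```

or in one shot from a YAML config with `costark report config.yaml`.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
rebuilds the piecewise EAC dipole models from the published HF, B3LYP and
MP2 equivalent charges (l = 1.14 Å), evaluates noiseless energies on a
seeded two-sided field sample, runs the segmented fit, and writes the
recomputed unsigned slope ratios |k1|/|k2| per method as JSON.
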