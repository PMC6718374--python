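# perfquant

Quantification of myocardial blood flow (MBF) from simultaneous PET–MR
first-pass perfusion, at the region-of-interest level: a digital
dual-bolus / dual-tracer perfusion phantom, Fermi-constrained
deconvolution of dynamic contrast-enhanced CMR curves, the
one-tissue-compartment (DeGrado) fit of ¹³N-ammonia PET time–activity
curves, and the agreement statistics that compare the two arms.

It is written for imaging scientists who have ROI curves — an arterial
input function (AIF) and one or more myocardial regions — rather than raw
scanner data, and who want the two modalities quantified with commensurable
conventions and compared with the field's standard statistics.

## Models

**Compartment phantom.** A well-mixed myocardial compartment of dispersion
volume V_d fed at flow Q = F·m (F in mL/g/min, m the tissue-mass
equivalent): dC_m/dt = (Q/V_d)(C_a − C_m). Knowing V_d and m calibrates
recovered rate constants to mL/g/min.

**CMR arm.** Fermi-constrained deconvolution: the tissue curve is modelled
as C_a ⊛ R with R(t) = F_A / (1 + e^{k(t−τ₀−τ_d)}), and MBF is the impulse
response at its onset, R(τ_d), by the central volume principle. The
dual-bolus AIF (dilute bolus, measured in the linear signal regime, scaled
by the dose ratio and foot-aligned to the neat injection) corrects AIF
saturation; in phantom mode the AIF is additionally rescaled so
∫AIF dt = ∫myo dt (indicator conservation).

**PET arm.** One-tissue-compartment model
C_t = (1−V_b)·K₁·∫C_a e^{−k₂(t−u)}du + V_b·C_a, fitted over the first
240 s to decay-corrected, frame-binned TACs (60 × 3 s + 8 × 15 s);
MBF = K₁.

**Agreement.** Pearson r (two-tailed), ICC(2,1) (two-way random effects,
absolute agreement, single measure, from the ANOVA mean squares), and
Bland–Altman bias ± 1.96·SD limits of agreement with the CMR − PET sign
convention; plus 16-segment AHA tables aggregated to LAD/RCA/LCX
territories and a global mean.

## Worked example

Simulate one phantom run at a ground-truth flow of 3 mL/g/min with the
default (realistic-noise) settings and quantify it with both arms:

```python
from perfquant import (PhantomConfig, simulate_protocol,
                       quantify_cmr_phantom, quantify_pet_phantom)

ds = simulate_protocol(PhantomConfig(flow=3.0, seed=7))
cmr = quantify_cmr_phantom(ds)
pet = quantify_pet_phantom(ds)
print(f"CMR (Fermi): MBF = {cmr.mbf:.3f} mL/g/min")
print(f"PET (1TC):   MBF = {pet.mbf:.3f} mL/g/min  "
      f"(K1={pet.params.K1:.3f}, k2={pet.params.k2:.3f}/min)")
```

```
CMR (Fermi): MBF = 2.573 mL/g/min
PET (1TC):   MBF = 3.014 mL/g/min  (K1=3.014, k2=2.997/min)
```

The PET fit recovers the truth within ~1%, and its k₂ equals the
compartment washout rate (3/min for the unit-ratio compartment at
3 mL/g/min) — the no-trapping consistency check. The CMR estimate reads
low: a Fermi kernel read at its onset understates the purely exponential
impulse response of a well-mixed compartment (see `docs/methods.md`), the
same direction of disagreement physical-phantom experiments show between
the two modalities.

A full sweep of the 1–5 mL/g/min protocol grid with the comparison layer:

```python
from perfquant import run_phantom_study

res = run_phantom_study(seed=1)
print(res.cmr_mbf)   # (0.940, 1.749, 2.526, 3.268, 4.015)
print(res.pet_mbf)   # (0.997, 2.042, 3.053, 4.142, 5.041)
a = res.agreement
print(f"r={a.pearson_r:.4f}  ICC={a.icc:.3f}  bias={a.bias:.3f} mL/g/min")
```

```
r=0.9997  ICC=0.900  bias=-0.555 mL/g/min
```

Both arms rise strictly with true flow and correlate almost perfectly,
while the Fermi arm's systematic under-reading produces the negative
cross-modality bias and an absolute-agreement ICC below the correlation —
the pattern the comparison machinery exists to expose.

The same workflows are available from the shell:

```sh
perfquant simulate --flow 3 --seed 7 --out run/
perfquant quant-pet --aif run/pet_tac_aif.csv --tissue run/pet_tac_myo.csv
perfquant compare cmr_table.csv pet_table.csv --plot ba.png
perfquant run --config pipeline.yaml
```

Curves are plain CSV (`time_s,value`, or
`frame_start_s,frame_duration_s,mean_activity` for TACs) with the unit and
provenance in `#` header comments; configs are YAML/JSON, schema-validated.

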