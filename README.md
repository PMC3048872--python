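# thermostab

Two-state thermal-denaturation analysis for protein calorimetry and
spectroscopy, built around the kind of study done on the regulatory
subunit of cAMP-dependent protein kinase (PKA RIα): a modular,
ligand-responsive protein whose heat-denatured state keeps a large amount
of ordered structure. The package answers the questions such a study
asks:

* What are the transition temperature and the calorimetric and van't
  Hoff enthalpies of the unfolding transition seen by differential
  scanning calorimetry (DSC), and is the transition two-state
  (ΔH/ΔH^VH ≈ 1)?
* Where is the midpoint of the optical (CD) melt, which need not agree
  with the calorimetric one?
* How much does a ligand (e.g. cAMP) stabilise the protein, expressed as
  a melting-temperature shift versus concentration, and what native-state
  dissociation constant explains it?
* How much enthalpy *should* complete unfolding release, predicted from
  buried surface area — and does the measured ΔH fall far enough below it
  to diagnose residual structure in the denatured state?

## The models

**DSC.** The excess molar heat capacity of a two-state transition
N ⇌ D is

    Cp_ex(T) = ΔH·ΔH^VH·K / (R·T²·(1+K)²),
    K(T)     = exp[(ΔH^VH/R)(1/Tm − 1/T)],

with `Tm` the half-conversion temperature, `ΔH` the calorimetric enthalpy
(the peak area) and `ΔH^VH` the van't Hoff enthalpy (the peak sharpness).
`TwoStateCalorimetryModel` fits all three by bounded least squares after
the raw scan has been buffer-subtracted, normalised to molar units, and
stripped of its chemical baseline (linear pre/post trends joined by an
iterated extent-of-conversion weighting).

**CD melts.** `CdMeltModel` fits a population-weighted average of sloping
native and denatured baselines with an apparent van't Hoff midpoint.

**Ligand linkage.** For a single saturable site on the native state,
`1/Tm0 − 1/Tm(L) = (R/ΔH0)·ln(1 + L/Kd)`; `TitrationModel` estimates
`(Tm0, Kd)` from a (concentration, Tm) series with ΔH0 fixed from DSC.

**Structure energetics.** From the apolar/polar surface area exposed on
complete unfolding (Shrake–Rupley ASA of the folded structure versus an
extended Gly-X-Gly reference):

    ΔCp    = (0.45·ΔASA_ap − 0.26·ΔASA_pol)/1000   kcal K⁻¹ mol⁻¹
    ΔH(60) = (31.4·ΔASA_pol − 8.44·ΔASA_ap)/1000   kcal mol⁻¹

extrapolated to any temperature by Kirchhoff's relation. The ratio of the
measured ΔH to the predicted full-unfolding ΔH(Tm) is the
residual-structure index: values around 0.5 mean roughly half the
structure survives heat denaturation.

All estimators follow scikit-learn conventions (`fit`, `predict`,
trailing-underscore fitted attributes) and compose with sklearn tooling;
thin functions (`fit_two_state`, `fit_cd_melt`, `fit_titration`, …)
wrap them for script use.

## Worked example

Simulate a noisy apo-protein scan (midpoint 62.5 °C, ΔH 111.6 kcal/mol,
ΔH^VH 96.3 kcal/mol, noise 0.1 kcal mol⁻¹ K⁻¹) and refit it end to end —
baseline removal included:

```sh
thermostab simulate --kind dsc --tm 62.5 --noise-sd 0.1 --seed 7 --out apo_scan.tsv
thermostab fit-dsc apo_scan.tsv
```

```json
{
  "converged": true,
  "tm_celsius": 62.498619441426115,
  "dh_cal_kcal": 108.9722845294207,
  "dh_vh_kcal": 97.64055058510729,
  "dh_ratio": 1.1160556129232007,
  "std_errors": {
    "tm_celsius": 0.00550523673176926,
    "dh_cal_kcal": 0.14858896519203124,
    "dh_vh_kcal": 0.16411195180699406
  },
  "n_points": 801
}
```

The midpoint comes back within 0.002 °C of the injected value; the
calorimetric enthalpy is ~2 % low because the chemical baseline had to be
estimated from the noisy flanks — the realistic cost of baseline removal.
The ratio ΔH/ΔH^VH ≈ 1.12 sits inside the two-state band (0.8–1.2).

The same from Python:

```python
import thermostab as ts

pred = ts.predict_energetics(dasa_ap=18746, dasa_pol=10598, tm_celsius=71.0)
print(round(pred.dcp_calc, 1), round(pred.dh_calc_at_tm))   # 5.7 237
print(round(ts.residual_structure_index(120.4, pred.dh_calc_at_tm), 2))  # 0.51
```

A measured ΔH of 120.4 kcal/mol against a predicted 237 kcal/mol for
complete unfolding says about half the fold never melts.

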