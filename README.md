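# pulmshear

Reduced-order (0D) pulmonary-artery hemodynamics and wall-shear-stress
biomarker analysis for chronic thromboembolic disease.

## The scientific problem

Chronic thromboembolic pulmonary hypertension (CTEPH) and its
normotensive precursor, chronic thromboembolic disease with
ventilation/perfusion (V/Q) mismatch (CTEPD), are under-diagnosed sequelae of
pulmonary embolism. Organized thrombi and microvascular remodeling alter the
flow field of the proximal pulmonary arteries, and the time-averaged wall
shear stress (TAWSS) there falls well before pressures rise: patients with
perfusion mismatches show markedly lower proximal TAWSS than controls, making
it a candidate non-invasive screening biomarker.

`pulmshear` is a desk-scale, fully seeded re-implementation of that analysis
chain for methodologists and modellers: every stage from boundary-condition
calibration to the diagnostic statistics is testable code, driven by a
synthetic three-group cohort generator (30 CTEPH / 30 CTEPD / 30 control by
default) calibrated to published clinical summary tables. No patient data or
imaging is required.

## The model

- **Arterial tree** — the proximal anatomy (MPA, LPA, RPA and descendants) is
  reduced to a rooted tree of straight segments with per-segment length and
  diameter. Generated trees satisfy Murray's bifurcation closure
  `D_p^γ = D_1^γ + D_2^γ` exactly.
- **Windkessel boundary conditions** — total pulmonary vascular resistance
  `R = (mPAP − PAWP)/CO` is apportioned over outlets as `R_i ∝ 1/D_i^2.25`
  and total compliance as `C_i ∝ D_i²`; each outlet carries a three-element
  RCR model (`Rp`, `C`, `Rd`) referenced to the wedge pressure. A damped
  fixed-point loop rescales total resistance and compliance until simulated
  mPAP and pulse pressure match the patient's right-heart-catheter record
  (default tolerance 2%); cardiac output is exact by construction because
  root inflow is imposed.
- **Pulsatile 0D solver** — Poiseuille segment resistances
  (`R = 8μL/πr⁴`, blood μ = 0.0035 Pa·s, ρ = 1060 kg/m³) driven by a
  half-sine systolic inflow derived from CO and HR; Windkessel capacitors
  advance by an implicit-Euler update; at least six cardiac cycles run until
  the cycle-mean root pressure is periodic, and metrics come from the final
  cycle.
- **Shear metrics** — quasi-steady Poiseuille wall shear `τ = 4μQ/πr³`;
  `TAWSS = (1/T)∫|τ|dt` and `OSI = ½(1 − |∫τ dt|/∫|τ|dt)`, aggregated to one
  patient value by luminal-area-weighted mean over MPA+LPA+RPA.
- **Diagnostics** — tie-corrected Kruskal–Wallis H, Dunn's post hoc z tests
  with Bonferroni correction, tie-safe Spearman ρ, ROC with the Mann–Whitney
  AUC identity (lower TAWSS = disease-positive), Youden-J optimal cutoff, and
  sensitivity/specificity/PPV/NPV with Wilson 95% intervals.

## Worked example

```sh
$ pulmshear cohort --seed 1 cohort.csv
wrote 90 patients to cohort.csv
$ pulmshear stats cohort.csv report.json
AUC=0.924 rho=-0.693 cutoff=33.80
```

The cohort is one seeded 30/30/30 draw from the calibrated group
distributions; `report.json` holds the full analysis. For this seed the
Kruskal–Wallis test on TAWSS gives H = 53.1 (p ≈ 3×10⁻¹²) with all three
Dunn–Bonferroni pairs significant; the ROC of TAWSS against mismatch status
has AUC 0.924, the Spearman correlation with binary mismatch status is
−0.693, and at the fixed 27.0 dyn/cm² cutoff this cohort shows sensitivity
0.63 and specificity 1.00. Single-cohort numbers fluctuate seed to seed;
replicate means are the stable quantities:

```sh
$ pulmshear replicate --replicates 100 --base-seed 1 reps.csv
mean AUC=0.934 rho=-0.709 sens@27=71.8%
```

The same chain is available as a library (`generate_cohort`,
`analyze_cohort`, `replicate_study`), and the mechanistic mode
(`pulmshear cohort --mode mechanistic ...`) runs the full tree → RCR tuning
→ pulsatile solve → shear pipeline for every patient instead of sampling
TAWSS directly.

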