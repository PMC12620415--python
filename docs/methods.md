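# Methods

This note documents the models, numerical choices, and design decisions in
`pulmshear`, and what its synthetic cohorts can and cannot say about real
patients.

## Scope of the reduction

The clinical analysis this package re-implements runs 3D patient-specific
CFD on segmented CT pulmonary angiograms. `pulmshear` deliberately replaces
the imaging and 3D stages with their reduced-order equivalents: the anatomy
becomes a per-segment (length, diameter) tree, the flow solver becomes a
lumped-parameter (0D) network, and wall shear stress becomes quasi-steady
Poiseuille shear. The boundary-condition calibration loop — the part of such
studies that actually determines the global hemodynamic load — is itself a
reduced-order computation in the source methodology, and is reproduced here
in full. Absolute proximal TAWSS magnitudes from 3D near-wall velocity
gradients are *not* reproducible in 0D (the 0D values are roughly one order
of magnitude lower); between-group structure and ratios are. The
quantitative diagnostic results therefore rest on the statistically
calibrated cohort mode (below), while the mechanistic mode demonstrates that
the modelling chain produces the right ordering and relative depression of
shear.

## Arterial tree

Segments carry a lumen diameter and length in cm; generation 0 is the main
pulmonary artery (MPA), its children the left and right PA. Generated trees
close Murray's law `D_p^γ = D_1^γ + D_2^γ` exactly at every bifurcation. The
γ default is 2.25, matching the exponent the boundary-condition stage uses
for resistance apportionment; the classic morphometric exponent 3.0 is a
parameter away. Asymmetry `a` splits the parent's `D^γ` into shares
`(1 ± a)/2`, with a seeded coin deciding which daughter gets the larger
share. Segment length defaults to 3 diameters, a typical proximal
pulmonary proportion. Three bifurcation generations (8 outlets) stand in
for the "proximal tree plus major branches" of the imaging-based models,
whose retained depth is not published; the count is configurable.

Disease remodeling rescales the whole tree geometrically to a target MPA
caliber (published medians: 30.5 mm CTEPH, 25.0 mm CTEPD, 23.0 mm control)
and, for diseased groups, halves the diameter of a seeded subset of outlets
(default fraction 0.4 CTEPH, 0.2 CTEPD) to emulate chronic thromboembolic
narrowing. Occlusion is applied to outlets, not the proximal vessels, so
proximal shear responds only through flow redistribution and the tuned
boundary conditions — consistent with the idea that proximal TAWSS reflects
downstream burden.

## Windkessel boundary conditions and tuning

Total resistance `(mPAP − PAWP)/CO` (converted to CGS; 1 Wood unit =
80 dyn·s/cm⁵, 1 mmHg = 1333.22 dyn/cm²) is distributed over outlets
inversely to `D^2.25`, so the parallel combination recovers the total
identically; total compliance is distributed proportionally to `D²`. Each
outlet's resistance splits into proximal and distal parts at a fixed
fraction `Rp : Rd = 0.1 : 0.9` — the split is not published; 10% proximal is
a common impedance-matching heuristic and is exposed in configuration. The
distal reference pressure is the wedge pressure (PAWP), the physiological
outflow pressure appearing in the PVR definition itself.

Initial total compliance is stroke volume / pulse pressure (stroke volume =
CO/HR); when systolic/diastolic pressures are unavailable the fallback sets
the RC time constant to 0.5 s. Tuning is a damped fixed-point iteration:
after each pulsatile solve, total resistance is rescaled by the ratio of
target to simulated transpulmonary gradient and total compliance by the
ratio of simulated to target pulse pressure. The map is nearly linear in
log-scale, so undamped updates converge in a handful of iterations;
oscillation halves the damping, and per-iteration factors are clamped to
[1/4, 4] so one bad early estimate cannot push the state into a numerically
unstable regime. Convergence requires both relative errors ≤ 2% (default)
within 20 iterations; non-convergence is reported, not raised. Cardiac
output and hence PVR need no tuning: inflow is imposed, and PVR follows from
the matched mPAP and the fixed PAWP.

The pulse pressure a flow-driven RCR system can produce is bounded: as
compliance→0 the pressure tracks `Q(t)·R`, giving
`PP_max ≈ (Q_peak/Q_mean)·(mPAP − PAWP) ≈ 4.5×` the gradient for the default
waveform, and as compliance→∞ a floor set by the proximal resistance share.
Targets outside this envelope cannot converge; the cohort generator's
coherence rules (below) keep sampled targets inside it except in rare tails,
and such patients are excluded with logged provenance rather than imputed.

## Pulsatile 0D solver

The network is a tree of Poiseuille segment resistances `8μL/πr⁴` (blood:
Newtonian, μ = 0.0035 Pa·s, ρ = 1060 kg/m³ — density is carried for
completeness; a purely resistive-capacitive network does not use it) with an
imposed root inflow and an RCR Windkessel at each outlet. Segment compliance
is omitted; all compliance is lumped at the outlets, matching the
distribution scheme being emulated.

The inflow waveform is a half-sine systole over 35% of the cycle and zero
diastole, scaled so the discrete cycle mean equals the prescribed CO
exactly. Only CO and HR are published inputs; the shape is a standard
pulmonary approximation and is configurable. A consequence: root inflow
never reverses, so proximal OSI is identically zero in mechanistic mode.

Time stepping: at each step the resistive subnetwork is solved exactly for
the current capacitor pressures by a Thevenin up-sweep/down-sweep (O(n));
capacitors then advance by an implicit-Euler update of
`dPc/dt = (Q_out − (Pc − P_d)/Rd)/C` with the outlet flow held at its
pre-step network value. Because the resistive solve is affine in
`(Q_in, Pc)`, the network response is precomputed once as a small matrix map
(m+1 basis solves for m outlets), making each step a mat-vec. The scheme is
unconditionally stable in the Windkessel leak term; the explicit
flow-redistribution coupling can destabilize only for extreme
parameters (compliance orders of magnitude below physiological), in which
case the solver raises a named instability error rather than returning
garbage.

Defaults: dt = 1 ms (rounded so a cycle is an integer number of steps),
minimum six cardiac cycles, maximum 20, periodic convergence declared when
the cycle-mean root pressure changes < 0.5% between cycles. Halving dt
changes mPAP by < 0.2% (verified in tests, the 0D analogue of a mesh
independence check). Cycle-mean flow conservation holds to < 0.5% at
periodicity. The published methodology states "steady-state" governing
equations while describing six-cycle pulsatile runs and cycle-averaged
metrics; this package implements the pulsatile reading, without which
TAWSS/OSI would be degenerate.

## Shear metrics

Signed quasi-steady Poiseuille shear `τ(t) = 4μQ(t)/πr³` stands in for the
3D WSS vector; no Womersley correction is applied (proximal pulmonary
Womersley numbers are large, so the quasi-steady waveform underestimates
amplitude attenuation, but cycle-averaged magnitudes — the quantity used —
are far less sensitive). TAWSS is the trapezoidal cycle mean of `|τ|` on the
uniform periodic grid (equal to the sample mean); OSI is
`½(1 − |∫τ|/∫|τ|)`, defined as 0 for the degenerate no-flow case and clipped
against floating-point cancellation. Patient-level values are
luminal-surface-area-weighted means (weight `πDL`) over MPA+LPA+RPA; the
published analysis reports one value per patient without stating its
reduction, and an area-weighted mean is the natural surrogate for a
surface-averaged field.

## Synthetic cohorts

**Statistical mode** draws patient TAWSS directly from lognormal
distributions quantile-matched to the published per-group median/Q1/Q3
(16.5 [13.31–20.44] CTEPH, 27.5 [24.00–34.00] CTEPD, 42.0 [34.00–48.50]
control, dyn/cm²): `μ = ln(median)`, `σ` = the mean of the two one-sided
log-quartile distances divided by z₀.₇₅ ≈ 0.6745. The lognormal family is a
choice — summaries alone cannot identify a family — made because these are
positive, right-skewed clinical quantities; when a printed IQR is
log-asymmetric the averaged σ splits the difference between the two printed
quartiles rather than hitting both. OSI is drawn from one shared
0.5·Beta(2, 8) distribution (median ≈ 0.09) for all groups, matching the
finding of no group effect in OSI. Mismatch scores for CTEPH/CTEPD come from
their published summaries; controls have none and are labelled
mismatch-negative, CTEPH and CTEPD mismatch-positive (60 positives vs 30
negatives in the default design).

**Catheter records** are sampled per field from the published hemodynamic
summaries, then made jointly coherent: the (dPAP, mPAP, sPAP) triple is
sorted; PAWP is capped at 80% of mPAP; pulse pressure is clamped into
1.2–3.5× the transpulmonary gradient (published group medians give ratios
1.6–2.1; independent draws occasionally compose triples no flow-driven
circulation could produce); PVR is recomputed as (mPAP − PAWP)/CO. Heart
rate, never published, is uniform on [60, 90] bpm.

**Mechanistic mode** chains, per patient: tree generation (seeded), disease
remodeling at the sampled MPA caliber, RCR tuning to the sampled catheter
record, pulsatile solve, shear aggregation. Tuning failures are excluded
with logged identity, never silently or by imputation.

What passing tests on these cohorts show: that the statistical machinery
reproduces the published discrimination statistics *given* group TAWSS
distributions matching the published summaries, and that the mechanistic
chain produces the observed ordering and relative shear depression from
anatomy and hemodynamics alone. What they do not show: anything about
imaging, segmentation, 3D flow features (secondary flows, recirculation,
regional OSI elevation), or the absolute shear magnitudes of real vessels.

## Statistics

Kruskal–Wallis H uses midranks with the standard tie correction and a
χ²(k−1) p-value; the all-tied degenerate case returns (0, 1). Dunn's z
statistics use the pooled-rank variance `N(N+1)/12 − Σ(t³−t)/(12(N−1))`,
two-sided normal p-values, and Bonferroni multiplication by the number of
pairs capped at 1. Spearman ρ is the Pearson correlation of midranks
(delegated to `scipy.stats.spearmanr`); correlating a continuous score with
a binary indicator is intentional — "mismatch status" is binary because
controls have no mismatch score. ROC analysis orients *lower* TAWSS as
disease-positive (required for a high-specificity *upper* normal range);
thresholds sit at midpoints between adjacent distinct scores plus ±∞
sentinels; AUC uses the Mann–Whitney identity with ties counted ½, which
equals the trapezoidal area under the empirical curve. Youden's J breaks
ties toward higher specificity, then lower threshold. Proportion CIs are
Wilson score intervals (the published analysis does not name its method).

The published report contains two internal inconsistencies, reproduced here
for transparency and excluded from quantitative targets: the printed NPV
(60.5%) disagrees with the 62.5% implied by its own sensitivity/specificity
at 60/30 prevalence, and some tabulated pairwise p-values contradict the
prose significance statements; the prose is taken as authoritative.

## Replication harness and problem sizes

`replicate_study` runs seeded statistical-mode cohorts (seeds
`base..base+n−1`) and reports replicate means and Monte-Carlo SEs of AUC,
Spearman ρ, and sensitivity at the fixed 27.0 dyn/cm² cutoff. The acceptance
script uses 500 replicates of the 30/30/30 design — enough to pin the
replicate means to ±0.002 (AUC) while running in seconds. The mechanistic
ordering test uses 90 patients per group: the CTEPD/control median gap is
≈ 0.16 log units against a patient-level log-spread of ≈ 0.4 (the `D³` law
amplifies diameter variability), so 30 per group would invert the ordering
by chance in roughly one run in eight, while 90 keeps that below ~2%.

## Known limitations

- No wave propagation, inertance, or fluid–structure interaction; pressure
  waveform *shapes* are Windkessel-like, not physiologic in fine detail.
- Proximal OSI is structurally zero in mechanistic mode (non-reversing
  imposed inflow); OSI group statistics are therefore only meaningful in
  statistical mode, mirroring the null finding they emulate.
- The Rp:Rd split, inflow shape, occlusion model, and aggregation rule are
  all unpublished details filled by documented defaults; each is exposed in
  configuration.
- Lognormal calibration matches medians and (averaged) quartiles only; tail
  behaviour beyond the IQR is extrapolation, which is why tail-sensitive
  published quantities (100% specificity, the exact Youden cutoff, H) are
  not quantitative targets.
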