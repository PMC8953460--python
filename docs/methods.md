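# Methods

This note documents the model, its parameterization, the numerical choices
and the known limitations of `antapbpk`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Compounds and inputs

Two analytes are modelled. **Antazoline** (free base, MW 265.35 g/mol) is a
monoprotic base: logP 3.16, pKa 9.43, fu 0.586, B/P 1.18, fu(mic) 0.88.
**Hydroxyantazoline (M2)**, the para-hydroxylated metabolite (MW 281.36),
is an ampholyte whose inputs are QSAR predictions: logP 2.57, pKa 9.2 and
10.3, fu 0.742, B/P 1 (assumed), total systemic clearance 12 L/h. The acid
pKa is assigned to the phenolic hydroxyl (10.3) and the base pKa to the
imidazoline (9.2); this assignment is not reported with the values, but the
imidazoline of the parent itself has pKa 9.43, which supports it. Clinical
doses are stated as antazoline **mesylate**; amounts are converted to free
base with the factor 265.35/361.46 ≈ 0.734 before entering the model. The
conversion is verified by a consistency identity: 73.4 mg / 80.5 L/h ≈
910 ng·h/mL, the clinically estimated exposure.

In vitro assay results (plasma binding, B/P, microsomal binding, hepatocyte
and HLM stability, recombinant CYP half-lives, UGT bounds) ship as a
validated panel fixture. The HLM and hepatocyte clearances are used only in
diagnostic cross-checks; the model's clearance is built from the
recombinant (Bactosomes) pathway data, because metabolite formation
requires pathway resolution. fu(mic) is stored but applied only in the HLM
cross-check — the recombinant CLint values are scaled directly.

## Tissue partitioning and Vss

Tissue:plasma partition coefficients use the Rodgers–Rowland
tissue-composition equations. For a moderate-to-strong base (and for an
ampholyte carrying a strong basic group) the unbound partition coefficient
in tissue T is

    Kpu_T = f_EW + f_IW·X_T/Y + Ka·[AP]_T·c_T/Y + (P·f_NL + (0.3P + 0.7)·f_NP)/Y

with X_T and Y the total:neutral species ratios at intracellular and plasma
pH (Henderson–Hasselbalch; ampholytes treated as two independent sites with
the zwitterion counted net-neutral), c_T the cationic:neutral ratio at
intracellular pH, P = 10^logP, and Ka the cation/acidic-phospholipid
association constant. Ka is back-calculated from the measured B/P through
erythrocyte partitioning, Kpu_BC = (B/P − (1 − Hct))/(Hct·fu). Neutral
species use the albumin-binding variant, with the protein term derived from
fu and clamped at zero. Kp = Kpu·fu.

Composition values (water/lipid fractions, acidic phospholipids, albumin
ratios, intracellular pH) are the published Rodgers–Rowland tables — rat
derived, the standard surrogate in human whole-body PBPK — shipped as
package data with a documented header and overridable by file.

Two boundary behaviours are deliberate:

- If the measured B/P is at or below the passive erythrocyte prediction,
  Ka is clamped to 0 with a warning (no detectable acidic-phospholipid
  binding); a hard error is raised only for B/P < 1 − Hct, which implies a
  negative erythrocyte concentration. This matters because the sensitivity
  screening samples B/P down to 0.55 = 1 − Hct exactly.
- The adipose neutral-lipid phase uses logP o:w directly, like every other
  tissue. The original method substitutes a vegetable-oil:water coefficient
  for adipose; since only logP o:w is reported for these compounds, the
  default applies it uniformly, and the olive-oil regression
  (log P_vo = 1.115·logP − 1.35) is available behind
  `adipose_vegetable_oil=True`. The choice moves antazoline's predicted
  Vss by roughly a third and the default is the variant consistent with
  the reported Vss values.

Vss (plasma-referenced, L/kg) = (V_plasma + Σ V_T·Kp_T + V_ery·E:P)/BW,
with E:P = (B/P − (1 − Hct))/Hct.

## Clearance

Whole-liver unbound intrinsic clearance per pathway:
CLint,u = CLint[µL/min/pmol] · ISEF · abundance[pmol/mg] · MPPGL[mg/g] ·
liver mass[g] → L/h. Defaults: MPPGL 40 mg/g, liver 1650 g and hepatic
blood flow 96.7 L/h for the 81-kg reference adult, abundances CYP2D6
8 pmol/mg and CYP2C19 14 pmol/mg — widely used IVIVE reference values, all
configurable. ISEF defaults to 1 per pathway because the Bactosomes ISEFs
actually applied in the source workflow are unpublished.

Hepatic blood clearance follows the well-stirred model,
CLH = Q_H·fu_B·CLint,u/(Q_H + fu_B·CLint,u) with fu_B = fu/(B/P). Whether
the reported IVIVE-scaled clearance (~70 L/h) is blood- or
plasma-referenced is ambiguous; this package reports the well-stirred
output itself (blood-referenced) as the "scaled CYP clearance" and carries
the plasma-referenced value (× B/P) in `ClearanceBreakdown` for the ODE
model and NCA consistency. The non-CYP gap between clinical clearance and
the IVIVE estimate is modelled as a 10 L/h plasma-referenced clearance
acting on venous blood (site not mechanistically resolved; venous
placement matches NCA plasma arithmetic). The metabolite's 12 L/h total
clearance is treated the same way, with no further tracked products.

Metabolite formation: CYP2D6 turnover splits 1:1 between M2 and the
N-dealkylated product M1 (a mass sink); CYP2C19 is assumed to form M2
entirely, following the statement that both pathways lead to the same
metabolite. The fraction of total parent elimination forming M2 is then
(0.5·CL_2D6 + CL_2C19)/CL_total, and the molar formation rate in the ODE is
the hepatic elimination rate × Σ share_i·mf_i × MW_M2/MW_parent.

## Whole-body model

Fourteen compartments per analyte: arterial and venous blood, lung (in
series with the full cardiac output), and eleven systemic tissues; gut,
spleen and pancreas drain into the liver. Each tissue is perfusion-limited:
V_T·dC_T/dt = Q_T·(C_art − C_T·(B/P)/Kp_T). Hepatic elimination is driven
by the unbound liver concentration (fu·C_liver/Kp_liver) through CLint,u,
which reproduces the well-stirred extraction at steady state (verified in
the suite to 2%). Amounts are tracked in mg; plasma concentration is the
venous blood concentration divided by B/P, reported in ng/mL. Venous blood
is the sampling site (70% of total blood volume; the arterial pool holds
the rest).

Reference physiology: 81-kg adult male, cardiac output 365 L/h, blood
5.6 L, hematocrit 0.45; organ volumes and flow fractions are standard adult
values with flow fractions summing to one across the perfused tissues
(there is no rest-of-body compartment, so the skin/muscle fractions absorb
the remainder). Volumes scale linearly and flows as BW^0.75.

The system is linear and time-invariant between dose boundaries; the
constant-coefficient matrix is assembled once per model and integrated with
LSODA (rtol 1e-8, atol 1e-9 mg) with hard restarts at every infusion
boundary. Mass balance (dose = amounts in body + cumulative elimination) is
carried as ledger states and closes to integrator tolerance (asserted at
≤0.1%, achieved near machine precision). Dose regimens: single 100-mg
bolus over 1 min (the single-dose healthy-volunteer scenario; the infusion
duration is not stated for that study and defaults to the 1-min bolus
practice of the multi-bolus studies), and up to three 100-mg boluses over
1 min with 2-min gaps (cumulative 100/200/300 mg arms).

## Virtual population

The generator emulates a North-European adult population:

- body weight lognormal (mean 81 kg M / 66 kg F, CV 15%), age normal,
  truncation at ±3 SD everywhere;
- allometric volumes/flows from body weight; an additional lognormal CV 10%
  on cardiac output applied to all flows jointly (so flows always sum to
  cardiac output);
- MPPGL lognormal CV 30%; CYP2C19 abundance lognormal CV 30%;
- CYP2D6 as a phenotype mixture — PM 8%, IM 30%, EM 59%, UM 3% with
  abundance multipliers 0/0.5/1/2 — plus lognormal CV 30% within phenotype.
  The clinical studies did not genotype; the mixture is the package's
  assumption for a North-European-like population, surfaced in
  `PopulationSpec`;
- metabolite systemic clearance lognormal CV 30% (no data; assumption);
- hematocrit normal (0.45 M / 0.40 F, SD 0.03).

Observation synthesis samples each simulated profile at the clinical sparse
schedule (pre-dose, 10, 30, 120 min, 24, 48 h) and applies proportional
lognormal error exp(N(0, σ)), σ = sqrt(ln(1 + CV²)) — median-unbiased, so
predicted/observed fold statistics are centred at 1. Values below the LLOQ
(default 1 ng/mL) are flagged, not dropped. What the generator does **not**
emulate: assay-specific error structure, covariate correlations beyond body
size (renal function, hepatic impairment), dose-stopping rules of the
patient study, or time-varying physiology. Tests passing on synthetic data
therefore validate the pipeline's internal consistency, not its clinical
calibration.

## NCA

Linear-up/log-down trapezoid by default (linear variant available). λz by
log-linear regression over the best terminal window: all windows of the
last n ≥ 3 positive concentrations after Tmax, selected by adjusted R² with
a 1e-4 tie tolerance preferring longer windows. AUC∞ extrapolates
C_last/λz from the observed (not fitted) last concentration. MRT is
infusion-corrected by TI/2; CL = Dose/AUC∞; Vss = CL·MRT. The average fold
difference is the geometric mean of per-point predicted/observed ratios
(the arithmetic variant is available behind a flag; which one the original
verification used is not stated).

One disposition subtlety: the noise-free simulated profile exhibits a
low-concentration redistribution tail (muscle/adipose), so the asymptotic
terminal slope is shallower than the clinically estimated half-life, which
derives from sparse samples in the 0–24 h window. The suite therefore
checks MRT against the clinical value directly and the half-life over the
1–8 h window where clinical sampling concentrates.

## Morris screening

Standard elementary-effects design: p = 4 levels, Δ = p/(2(p−1)) = 2/3,
r trajectories of k+1 points (default r = 100, one repetition), random
base levels, directions and coordinate order, seed-reproducible. EEs are
computed on the unit scale; µ* = mean |EE|, σ = SD (ddof = 1); trajectories
yielding non-finite endpoints are dropped with a warning and counted.

The packaged application screens the six metabolite inputs over uniform
uncertainty ranges — logP 1.5–3.5, both pKa 6–14, B/P 0.55–2, clearance
2–80 L/h, fu 0.1–1 — against the metabolite's Cmax, AUC0–24 and Tmax from
a single 100-mg dose to the reference subject (the dosing scenario behind
the original screening is unstated; single-dose reference is the package's
choice, configurable). Independent uniform sampling can place the "acid"
pKa below the "base" pKa; such points are passed through unchanged — the
species-fraction model remains well defined — and are rejected only if Kp
prediction fails. Note that B/P acts directly on plasma concentration
(C_plasma = C_blood/(B/P)) as well as on partitioning, so it can outrank
clearance for Cmax even though clearance dominates the exposure endpoints.

## Problem sizes and tolerances

Defaults used by the shipped tests and the acceptance script: 100-subject
virtual trials on a ~520-point output grid over 48 h; Morris screening at
20 trajectories (140 model evaluations) in the test suite and 100 in the
full workflow. Golden-value tolerances: ±20% on the parent Vss and the
scaled CYP clearance, ±25% on the metabolite Vss and the trial median AUC —
acknowledging that the proprietary implementation's tissue-composition
tables, ISEFs and abundance distributions are unpublished, so exact
agreement is not attainable from the printed inputs alone.

## Known limitations

- Perfusion-limited distribution only; no permeability-limited organs, no
  transporters, no saturable kinetics, no renal mechanistic model (non-CYP
  routes are lumped into the additional clearance).
- M1 is a mass sink; only M2 is tracked.
- No oral absorption and no pharmacodynamic (ECG) linkage.
- The CYP2D6 phenotype structure is assumed, not fitted; all
  inter-individual variability magnitudes are assumptions surfaced in the
  population specification.
- The population AUC fold spread (max/min over 100 subjects) is a range
  statistic of a heavy-tailed mixture and varies substantially between
  seeds; the phenotype-mixture backbone (UM-to-PM clearance ratio) is
  ~7.5-fold.
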