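# antapbpk

Whole-body physiologically based pharmacokinetic (PBPK) model of
**antazoline** — a first-generation antihistamine used intravenously to
terminate paroxysmal atrial fibrillation — and its pharmacologically
interesting **hydroxy metabolite (hydroxyantazoline, M2)**.

Antazoline's disposition is poorly characterized: clinical PK data are
sparse, and the metabolite may contribute to the drug's cardiac effect. This
package builds the full chain from in vitro and QSAR inputs to simulated
plasma concentration–time profiles, without any proprietary simulator:

- **Mechanistic tissue partitioning** (`antapbpk.tissue`) — Rodgers–Rowland
  equations for tissue:plasma partition coefficients Kp from logP, pKa, fu
  and the blood:plasma ratio, with the cation/acidic-phospholipid
  association constant calibrated from erythrocyte partitioning;
  Vss = (V_plasma + Σ V_T·Kp_T + V_ery·E:P)/BW.
- **IVIVE clearance scaling** (`antapbpk.ivive`) — recombinant CYP2D6 and
  CYP2C19 intrinsic clearances (µL/min/pmol) scaled by enzyme abundance,
  MPPGL and liver mass, passed through the well-stirred liver model
  CLH = Q_H·fu_B·CLint,u/(Q_H + fu_B·CLint,u), plus a non-CYP "additional"
  systemic clearance derived as the clinical-minus-IVIVE gap.
- **Coupled parent+metabolite ODE system** (`antapbpk.engine`) — 14
  perfusion-limited compartments per analyte, portal drainage into the
  liver, multi-bolus IV regimens, metabolite formation as a fixed molar
  fraction of hepatic turnover (CYP2D6 split 1:1 to M2), full mass-balance
  ledger.
- **Virtual populations** (`antapbpk.population`) — allometric body-size
  scaling, lognormal variability on liver scalars, and a CYP2D6 phenotype
  mixture (PM/IM/EM/UM) that drives the large observed spread in exposure;
  synthetic sparse/noisy observation sets for exercising verification.
- **NCA and verification metrics** (`antapbpk.nca`) — linear-up/log-down
  AUC, best-window λz, CL, MRT, Vss, average fold difference, AUC fold
  spread.
- **Morris sensitivity screening** (`antapbpk.morris`) — elementary-effects
  screening (µ*, σ) of the metabolite model parameters over their
  uncertainty ranges.

## Worked example

Simulate the single-dose healthy-volunteer scenario (100 mg antazoline
mesylate IV over 1 min) for the reference adult:

```
$ antapbpk simulate --preset elephant1 --duration 12 --out demo
$ column -t -s, demo/nca.csv
```

```
analyte            auc_last  auc_inf  cmax    tmax   t_half  cl     mrt   vss
antazoline         661.9     702.8    7978.0  0.017  3.63    104.5  2.94  307.3
hydroxyantazoline  1233.9    3687.2   167.1   0.508  20.9          29.9
```

Reading the antazoline row: a 100-mg mesylate dose is 73.4 mg of free base;
at the model's total plasma clearance of ~102 L/h that gives an exposure of
~720 ng·h/mL over 0–∞ (here 703 from the 12-h window), a sharp end-of-bolus
peak near 8000 ng/mL, and an NCA volume of ~307 L — all close to the
clinically estimated 80.5 L/h, ~910 ng·h/mL and 315 L. The metabolite peaks
at ~167 ng/mL half an hour after dosing and persists much longer than the
parent (12 L/h clearance against a ~200 L volume), consistent with the
hypothesis that it sustains the drug's late cardiac effect.

Population and sensitivity workflows:

```
antapbpk population --n 100 --seed 1 --preset elephant1 --out pop
antapbpk gsa --trajectories 100 --seed 1 --out gsa
```

`pop/summary.json` holds the median AUC and max/min AUC fold spread;
`gsa/morris.csv` ranks the metabolite parameters by µ* (systemic clearance
dominates the metabolite's exposure endpoints).

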