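# Antazoline in vitro blood-binding and metabolic-stability panel.
# Dispersion is SD for binding assays and SE for clearance/half-life assays.
compound: antazoline
assays:
  blood_plasma_ratio:    {value: 1.18,  dispersion: 0.0161,  units: ratio}
  fu_plasma:             {value: 0.586, dispersion: 0.0109,  units: fraction}
  fu_mic:                {value: 0.88,  dispersion: 0.00563, units: fraction}
  hepatocyte_clint:      {value: 21.1,  dispersion: 2.21,    units: uL/min/1e6 cells}
  hepatocyte_half_life:  {value: 65.8,  dispersion: 0.0,     units: min}
  hlm_clint:             {value: 97.4,  dispersion: 8.63,    units: uL/min/mg}
  hlm_half_life:         {value: 14.2,  dispersion: 0.0,     units: min}
  cyp2d6_half_life:      {value: 0.56,  dispersion: 0.0,     units: min}
  cyp2c19_half_life:     {value: 51.0,  dispersion: 2.84,    units: min}
  cyp2c8_half_life:      {value: 1100.0, dispersion: 4210.0, units: min}
  ugt_clint_upper_bound: {value: 5.8,   dispersion: 0.0,     units: uL/min/mg}
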