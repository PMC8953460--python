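# Tissue composition inputs for the Rodgers-Rowland mechanistic Kp equations.
# Fractional volumes of extracellular/intracellular water, neutral lipids and
# neutral phospholipids; acidic phospholipid concentration in mg/g tissue;
# tissue:plasma albumin concentration ratio (used for neutral/acidic species);
# intracellular pH.  Values are the published Rodgers-Rowland composition
# tables (rat-derived, the standard surrogate in human whole-body PBPK).
# Special rows: "blood_cells" (erythrocytes; f_water_extra unused) and
# "plasma" (water and lipid content of plasma itself).
tissue,f_water_extra,f_water_intra,f_neutral_lipid,f_neutral_phospholipid,acidic_phospholipid_mg_g,albumin_ratio,pH_intra
adipose,0.135,0.017,0.853,0.0016,0.40,0.049,7.0
bone,0.100,0.346,0.017,0.0017,0.67,0.100,7.0
brain,0.162,0.620,0.039,0.0015,0.40,0.048,7.0
gut,0.282,0.475,0.038,0.0125,2.41,0.158,7.0
heart,0.320,0.456,0.014,0.0111,2.25,0.157,7.0
kidney,0.273,0.483,0.012,0.0242,5.03,0.130,7.0
liver,0.161,0.573,0.014,0.0240,4.56,0.086,7.0
lung,0.336,0.446,0.022,0.0128,3.91,0.212,7.0
muscle,0.118,0.630,0.010,0.0072,1.53,0.064,7.0
pancreas,0.120,0.664,0.041,0.0093,1.67,0.060,7.0
skin,0.382,0.291,0.060,0.0044,1.32,0.277,7.0
spleen,0.207,0.579,0.0077,0.0113,3.18,0.097,7.0
blood_cells,0.0,0.603,0.0017,0.0029,0.50,0.0,7.22
plasma,0.945,0.0,0.0035,0.00225,0.0,1.0,7.4
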