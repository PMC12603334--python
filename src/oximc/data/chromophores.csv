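# Chromophore absorption coefficients [1/mm] at the four design wavelengths.
# O2Hb/HHb: fully (de)oxygenated whole blood at 150 g Hb/L, from compiled
#   molar extinction spectra (mu_a = 2.303*eps*C_Hb); multiply by the blood
#   volume fraction C_b of a layer.
# water: pure-water absorption tabulations (visible/NIR window).
# melanin: melanosome interior, mu_a[cm^-1] = 1.70e12 * lambda^-3.48;
#   multiply by melanosome volume fraction C_Mel (epidermis only).
# baseline: bloodless, waterless tissue, 0.244 + 85.3*exp(-(l-154)/66.2) cm^-1.
wavelength,mu_a_O2Hb,mu_a_HHb,mu_a_water,mu_a_melanin,mu_a_baseline
624,0.45310,3.26705,0.00029,31.8571,0.03144
660,0.17117,1.72809,0.00040,26.2081,0.02849
850,0.56665,0.37025,0.00433,10.8660,0.02463
940,0.65020,0.37139,0.02674,7.6553,0.02446
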