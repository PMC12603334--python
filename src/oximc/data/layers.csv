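# Layered skin geometry and composition (surface downward).
# n: refractive index; d_t_mm: thickness (inf = semi-infinite terminal);
# C_b/C_w: blood/water volume fractions; v_d_mm: vessel diameter;
# pulsatile: whether C_b is modulated by the cardiac phase.
# Muscle composition is blank: its absorption comes from the mu_a_direct
# column of scattering.csv (ex-vivo tissue measurements) instead of mixing.
name,n,d_t_mm,C_b,C_w,v_d_mm,pulsatile
epidermis,1.33,0.27,0.0,0.20,0.0,no
capillary_loops,1.37,0.15,0.004,0.65,0.01,yes
upper_plexus,1.40,0.08,0.02,0.65,0.02,yes
reticular_dermis,1.40,1.2,0.004,0.65,0.02,yes
deep_plexus,1.40,0.50,0.04,0.65,0.04,yes
hypodermis,1.44,0.55,0.03,0.65,0.05,yes
muscle,1.37,inf,,,0.0,no
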