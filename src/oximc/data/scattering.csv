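# Per-layer scattering coefficient mu_s [1/mm] and anisotropy g.
# Derived from reduced-scattering power laws mu_s' = a*(500/lambda)^b
# (epidermis a=6.0 b=1.3; dermal layers a=4.6 b=1.3; hypodermis a=1.31
# b=0.68; muscle a=1.1 b=0.93, all mm^-1) with g = 0.62 + 2.9e-4*lambda
# for epidermis/dermis and fixed g for hypodermis (0.80) / muscle (0.90).
# mu_a_direct [1/mm]: direct absorption for layers without a composition
# mix (muscle, ex-vivo tissue measurements); blank elsewhere.
layer,wavelength,mu_s,g,mu_a_direct
epidermis,624,22.6012,0.8010,
epidermis,660,22.1750,0.8114,
epidermis,850,22.5469,0.8665,
epidermis,940,24.5891,0.8926,
capillary_loops,624,17.3276,0.8010,
capillary_loops,660,17.0008,0.8114,
capillary_loops,850,17.2859,0.8665,
capillary_loops,940,18.8516,0.8926,
upper_plexus,624,17.3276,0.8010,
upper_plexus,660,17.0008,0.8114,
upper_plexus,850,17.2859,0.8665,
upper_plexus,940,18.8516,0.8926,
reticular_dermis,624,17.3276,0.8010,
reticular_dermis,660,17.0008,0.8114,
reticular_dermis,850,17.2859,0.8665,
reticular_dermis,940,18.8516,0.8926,
deep_plexus,624,17.3276,0.8010,
deep_plexus,660,17.0008,0.8114,
deep_plexus,850,17.2859,0.8665,
deep_plexus,940,18.8516,0.8926,
hypodermis,624,5.6340,0.8000,
hypodermis,660,5.4231,0.8000,
hypodermis,850,4.5660,0.8000,
hypodermis,940,4.2640,0.8000,
muscle,624,8.9519,0.9000,0.100
muscle,660,8.4969,0.9000,0.085
muscle,850,6.7155,0.9000,0.045
muscle,940,6.1154,0.9000,0.060
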