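# Photodiode relative spectral sensitivity at the design wavelengths.
wavelength,factor
624,1.0
660,1.0
850,1.0
940,1.0
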