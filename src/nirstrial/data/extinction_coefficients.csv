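# Decadic specific extinction coefficients of hemoglobin at the two source
# wavelengths, scaled to 1/(umol/l)/mm so that MBLL inversion yields
# concentration changes directly in umol/l for source-detector distances in mm.
wavelength_nm,chromophore,epsilon_per_uM_per_mm
760,o2hb,5.860e-05
760,hhb,1.548e-04
870,o2hb,1.154e-04
870,hhb,7.910e-05
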