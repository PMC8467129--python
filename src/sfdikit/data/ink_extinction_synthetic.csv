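# Synthetic ink extinction fixture: absorption coefficient of India-ink stock
# per percent volume fraction, mm^-1 / %vf. Spectrally plausible stand-in
# values, NOT measured constants of any specific ink batch.
wavelength_nm,mua_per_pct_vf
460,2.10
503,2.20
527,2.30
630,2.50
658,2.55
675,2.60
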