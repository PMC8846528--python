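energy_MeV,range_phits_mm,range_srim_mm
80,59,58
160,199,197
240,389,395
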