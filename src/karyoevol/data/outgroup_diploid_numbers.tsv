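species	diploid_number
Sternopygus_macrurus	52
Rhamphichthys_rostratus	50
Gymnorhamphichthys_rondoni	50
Steatogenys_elegans	50
Hypopygus_lepturus	50
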