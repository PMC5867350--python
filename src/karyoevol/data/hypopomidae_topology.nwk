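(Sternopygus_macrurus,((Rhamphichthys_rostratus,Gymnorhamphichthys_rondoni)Rhamphichthyidae,((Steatogenys_elegans,Hypopygus_lepturus)Steatogenys_clade,((Brachyhypopomus_brevirostris,Brachyhypopomus_hendersoni)T,((Brachyhypopomus_regani,Brachyhypopomus_batesi)M,((Brachyhypopomus_bennetti,Brachyhypopomus_walteri)K,(Brachyhypopomus_flavipomus,((Brachyhypopomus_gauderio,Brachyhypopomus_pinnicaudatus)J,(Brachyhypopomus_beebei,Brachyhypopomus_hamiltoni)H)2)C)B)A)Brachyhypopomus)Hypopomidae)Rhamphichthyoidea)Root;
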