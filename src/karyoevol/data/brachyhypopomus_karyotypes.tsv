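species	sex	diploid_number	karyotype_formula	ch_bands	sex_system
Brachyhypopomus_hamiltoni	unspecified	36	6m-sm/30st-a	cen:all;dist:7q
Brachyhypopomus_brevirostris	unspecified	38	38st-a	cen:all;dist:6p;dist:9q;dist:13q;dist:17q;dist:18q;dist:19q;int:12q;int:14q;int:15q
Brachyhypopomus_hendersoni	unspecified	38	34m-sm/4st-a	cen:all;pericen:1p;pericen:5p;pericen:6p;pericen:14p;pericen:19p;prox:8q;prox:9q;prox:10q;prox:11q
Brachyhypopomus_regani	unspecified	38	14m-sm/24st-a	cen:all;int:12q
Brachyhypopomus_batesi	unspecified	40	38m-sm/2st-a	cen:all;int:2q;prox:7q;dist:9p
Brachyhypopomus_beebei	unspecified	40	8m-sm/32st-a	cen:all
Brachyhypopomus_bennetti	unspecified	40	2m-sm/38st-a	cen:all;band:1p
Brachyhypopomus_walteri	unspecified	40	2m-sm/38st-a	cen:all;band:1p;int:3q;dist:4q;dist:6q;dist:7q;dist:8q;dist:9q;dist:10q;dist:12q;dist:13q;dist:14q;dist:17q;dist:18q;dist:20q
Brachyhypopomus_pinnicaudatus	male	41	1m-sm/40st-a	cen:all;band:1q	X1X1X2X2/X1X2Y
Brachyhypopomus_pinnicaudatus	female	42	42st-a	cen:all;band:1q	X1X1X2X2/X1X2Y
Brachyhypopomus_gauderio	male	41	1m-sm/40st-a	cen:all	X1X1X2X2/X1X2Y
Brachyhypopomus_gauderio	female	42	42st-a	cen:all	X1X1X2X2/X1X2Y
Brachyhypopomus_flavipomus	male	43	1m-sm/42st-a	cen:all;dist:15q	X1X1X2X2/X1X2Y
Brachyhypopomus_flavipomus	female	44	44st-a	cen:all;dist:15q	X1X1X2X2/X1X2Y
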