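# Mono and combined RA drug therapies as clamp sets on the fixture model.
# clamp: 0 = inhibit target, 1 = activate target.
# Targets absent from the fixture (e.g. IL1B, CD28, TLR4, Calcineurin, RAC1)
# deliberately exercise the skip-with-warning path of the screen.
drug	target	clamp
Sarilumab	IL6R_sig	0
Tocilizumab	IL6R_sig	0
Etanercept	TNF	0
Infliximab	TNF	0
Adalimumab	TNF	0
Golimumab	TNF	0
Certolizumab_Pegol	TNF	0
Tofacitinib	JAK1	0
Baricitinib	JAK1	0
Itacitinib	JAK1	0
Secukinumab	IL17A	0
Andecaliximab	MMP9	0
Celastrol	MMP9	0
Imatinib	PDGFA	0
Methotrexate	IKBA_NFKB_RELA	0
Methotrexate	PDGFA	0
Methotrexate	IL1B	0
Anakinra	IL1B	0
Methotrexate_plus_Sarilumab	IKBA_NFKB_RELA	0
Methotrexate_plus_Sarilumab	PDGFA	0
Methotrexate_plus_Sarilumab	IL1B	0
Methotrexate_plus_Sarilumab	IL6R_sig	0
Abatacept	CD28	0
Hydroxychloroquine	TLR4	0
Cyclosporine	Calcineurin	0
Azathioprine	RAC1	0
Zoledronic_acid	CAV1_rna	0
Pamidronate	CAV1_rna	0
Incadronate	CAV1_rna	0
GSK2618960	IL7	0
T-5224	FOS	0
T-5224	JUN	0
Acitretin	FOS	0
Acitretin	JUN	0
Batimastat	MMP3	0
666-15	CREB1	0
AS1842856	FOXO1	0
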