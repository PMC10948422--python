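region	measure	adjusted	direction	or	or_lci95	or_uci95	beta	se	pvalue	p_fdr
lingual	SA	no	forward	1.0004	1.0001	1.0007			0.0086
parahippocampal	SA	no	forward	1.0023	1.0003	1.0043			0.0226
pericalcarine	SA	no	forward	1.0005	1.0001	1.0010			0.0203
lingual	SA	yes	forward	1.0005	1.0001	1.0009			0.0272
middle temporal	SA	yes	forward	1.0009	1.0003	1.0016			0.0037
inferior temporal	TH	no	forward	0.1954	0.0584	0.6538			0.008	0.0907
lateral occipital	TH	no	forward	0.1922	0.0648	0.5698			0.0029	0.0493
lateral orbitofrontal	TH	no	forward	0.0714	0.0156	0.3277			0.0007	0.0238
caudal anterior cingulate	TH	no	forward	0.4266	0.1916	0.9500			0.037
frontal pole	TH	no	forward	0.4073	0.1720	0.9620			0.0406
fusiform	TH	no	forward	0.0933	0.0114	0.7662			0.0273
pars orbitalis	TH	no	forward	0.1401	0.0280	0.6827			0.0149
pars triangularis	TH	no	forward	0.2053	0.0457	0.9214			0.0387
lateral orbitofrontal	TH	yes	forward	0.0750	0.0088	0.6368			0.0176
pericalcarine	TH	yes	forward	25.1309	1.9890	317.5326			0.0127
caudal middle frontal	TH	no	reverse				0.0082	0.0153	0.0163
inferior parietal	TH	no	reverse				0.0099	0.0047	0.0364
medial orbitofrontal	TH	no	reverse				0.0130	0.0057	0.0222
bankssts	TH	yes	reverse				-0.0091	0.0044	0.0400
superior temporal	TH	yes	reverse				0.0099	0.0046	0.0329
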