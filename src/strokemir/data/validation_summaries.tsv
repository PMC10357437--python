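target	group	mean	sem	n
hsa-let-7e-5p	stroke	0.582	0.143	20
hsa-let-7e-5p	healthy	-0.0005	0.164	20
hsa-miR-17-5p	stroke	0.509	0.147	20
hsa-miR-17-5p	healthy	0.0025	0.135	20
hsa-miR-185-5p	stroke	0.87	0.221	20
hsa-miR-185-5p	healthy	-0.004	0.139	20
hsa-miR-218-5p	stroke	-0.0685	0.273	20
hsa-miR-218-5p	healthy	0.002	0.244	20
hsa-miR-222-3p	stroke	0.244	0.123	20
hsa-miR-222-3p	healthy	-0.0005	0.247	20
hsa-miR-451a	stroke	-0.756	0.243	20
hsa-miR-451a	healthy	-0.0025	0.359	20
hsa-miR-487b-3p	stroke	-0.693	0.157	20
hsa-miR-487b-3p	healthy	0.001	0.332	20
hsa-miR-9-5p	stroke	0.138	0.301	20
hsa-miR-9-5p	healthy	-0.0005	0.163	20
hsa-miR-124-3p	stroke	-0.552	0.207	20
hsa-miR-124-3p	healthy	0.0035	0.168	20
hsa-miR-221-3p	stroke	0.0055	0.197	20
hsa-miR-221-3p	healthy	0.0035	0.248	20
hsa-miR-126-3p	stroke	0.064	0.356	20
hsa-miR-126-3p	healthy	0.0025	0.185	20
hsa-miR-130a-3p	stroke	0.592	0.34	20
hsa-miR-130a-3p	healthy	-0.001	0.316	20
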