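family	species	concentration_uM	diameter_mm	se_mm	level
Gramineae	Digitaria sanguinalis	100	0.61	0.15	+
Gramineae	Digitaria sanguinalis	500	2.24	0.16	++
Gramineae	Digitaria sanguinalis	1000	2.59	0.09	++
Gramineae	Microstegium vimineum	100	2.49	0.13	++
Gramineae	Microstegium vimineum	500	3.06	0.10	+++
Gramineae	Microstegium vimineum	1000	4.23	0.66	+++
Gramineae	Zea mays	100	2.10	0.16	++
Gramineae	Zea mays	500	3.60	0.83	+++
Gramineae	Zea mays	1000	5.49	0.29	+++
Gramineae	Oryza sativa	100	1.29	0.09	++
Gramineae	Oryza sativa	500	2.09	0.07	++
Gramineae	Oryza sativa	1000	2.10	0.07	++
Compositae	Solidago canadensis	100	2.10	0.67	++
Compositae	Solidago canadensis	500	3.19	1.51	+++
Compositae	Solidago canadensis	1000	3.60	0.69	+++
Compositae	Ageratina adenophora	100	3.88	0.34	+++
Compositae	Ageratina adenophora	500	5.94	1.17	+++
Compositae	Ageratina adenophora	1000	7.25	1.69	+++
Compositae	Youngia japonica	100	1.68	0.13	++
Compositae	Youngia japonica	500	3.04	0.21	+++
Compositae	Youngia japonica	1000	3.78	0.22	+++
Oxalidaceae	Oxalis corniculata	100	2.55	0.08	++
Oxalidaceae	Oxalis corniculata	500	3.79	0.24	+++
Oxalidaceae	Oxalis corniculata	1000	4.20	0.29	+++
Solanaceae	Nicotiana tabacum	100	1.58	0.10	++
Solanaceae	Nicotiana tabacum	500	2.87	0.60	++
Solanaceae	Nicotiana tabacum	1000	4.84	2.05	+++
Malvaceae	Gossypium barbadense	100	1.63	0.18	++
Malvaceae	Gossypium barbadense	500	1.96	0.11	++
Malvaceae	Gossypium barbadense	1000	2.61	0.17	++
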