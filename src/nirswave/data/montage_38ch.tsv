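channel	source	detector	hemisphere	region
CH01	S1	D1	left	PFC
CH02	S2	D1	left	PFC
CH03	S1	D2	left	PFC
CH04	S2	D2	left	DLPFC
CH05	S3	D2	left	DLPFC
CH06	S3	D3	left	DLPFC
CH07	S4	D3	left	SFC
CH08	S4	D4	left	SFC
CH09	S5	D4	left	SFC
CH10	S5	D5	left	PMC
CH11	S6	D5	left	PMC
CH12	S5	D6	left	PMC
CH13	S6	D6	left	M1
CH14	S7	D6	left	M1
CH15	S7	D7	left	M1
CH16	S8	D7	left	S1
CH17	S8	D8	left	S1
CH18	S9	D8	left	OC
CH19	S9	D7	left	OC
CH20	S10	D9	right	PFC
CH21	S11	D9	right	PFC
CH22	S10	D10	right	PFC
CH23	S11	D10	right	DLPFC
CH24	S12	D10	right	DLPFC
CH25	S12	D11	right	DLPFC
CH26	S13	D11	right	SFC
CH27	S13	D12	right	SFC
CH28	S14	D12	right	SFC
CH29	S14	D13	right	PMC
CH30	S15	D13	right	PMC
CH31	S14	D14	right	PMC
CH32	S15	D14	right	M1
CH33	S16	D14	right	M1
CH34	S16	D15	right	M1
CH35	S17	D15	right	S1
CH36	S17	D16	right	S1
CH37	S18	D16	right	OC
CH38	S18	D15	right	OC
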