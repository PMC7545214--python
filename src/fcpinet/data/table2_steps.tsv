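donor_subunit	donor_site	acceptor_subunit	acceptor_site	distance_A	leaflet
FCPI-18	406	FCPI-17	405	14.7	lumenal
FCPI-17	404	FCPI-6	412	18.9	lumenal
FCPI-6	411	PsaA	817	14.2	lumenal
FCPI-18	405	FCPI-7	404	20.4	lumenal
FCPI-7	411	PsaJ	102	11.8	lumenal
FCPI-19	405	FCPI-8	409	18.0	lumenal
FCPI-8	405	PsaB	834	19.4	lumenal
FCPI-20	405	FCPI-8	404	18.9	lumenal
FCPI-8	405	PsaB	834	19.4	lumenal
FCPI-21	405	FCPI-9	409	21.1	lumenal
FCPI-9	409	FCPI-10	409	9.5	lumenal
FCPI-10	410	PsaB	410	14.4	lumenal
FCPI-11	409	PsaB	815	22.2	lumenal
FCPI-1	410	PsaI	301	11.6	lumenal
FCPI-2	405	PsaI	204	21.4	lumenal
FCPI-13	410	FCPI-3	409	16.1	lumenal
FCPI-3	408	PsaI	204	10.7	lumenal
FCPI-24	413	FCPI-15	405	15.5	lumenal
FCPI-15	412	FCPI-4	412	13.0	lumenal
FCPI-4	413	PsaA	818	24.7	lumenal
FCPI-21	421	FCPI-9	401	9.8	stromal
FCPI-9	403	FCPI-8	400	17.9	stromal
FCPI-8	406	PsaR	201	11.0	stromal
FCPI-11	403	PsaB	811	13.0	stromal
FCPI-2	406	PsaL	401	17.6	stromal
FCPI-12	401	FCPI-3	406	16.9	stromal
FCPI-3	407	PsaA	845	12.5	stromal
FCPI-13	407	FCPI-4	400	17.2	stromal
FCPI-4	416	PsaA	821	13.5	stromal
FCPI-14	406	FCPI-4	400	17.7	stromal
FCPI-4	416	PsaA	821	13.5	stromal
FCPI-22	411	FCPI-15	401	14.6	stromal
FCPI-15	406	FCPI-5	400	21.0	stromal
FCPI-5	403	PsaA	821	17.2	stromal
FCPI-16	406	FCPI-6	401	18.7	stromal
FCPI-6	403	PsaA	812	25.7	stromal
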