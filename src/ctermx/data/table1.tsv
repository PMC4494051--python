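# Catalog of the 55 Saccharomyces genes with a C-terminal addition via stop codon loss
# (54 point/frameshift additions plus the YOL058W putative deletion-mediated fusion).
# Columns: systematic_name standard_name species outgroup_len_aa added_aa new_aa mutation_class n_alleles ribo_evidence total_evidence
systematic_name	standard_name	species	outgroup_len_aa	added_aa	new_aa	mutation_class	n_alleles	ribo_evidence	total_evidence
YAL005C	SSA1	S.cer	643	18	49	frameshift	2	strong	strong
YBR014C	GRX7	S.par	204	15	22	frameshift	3	strong	strong
YBR046C	ZTA1	S.par	335	26	30	frameshift	2	strong	strong
YBR194W	AIM4	S.par	124	4	5	frameshift	2	moderate	strong
YBR264C	YPT10	S.par	200	10	15	frameshift	2	strong	strong
YCR076C	FUB1	S.cer	243	11	22	frameshift	2	strong	strong
YDL027C	NA	S.par	421	3	4	frameshift	2	moderate	strong
YDL056W	MBP1	S.par	834	3	3	point	3	strong	strong
YDL175C	AIR2	S.cer	343	3	15	frameshift	2	strong	strong
YDR062W	LCB2	S.cer	562	7	7	frameshift	2	strong	strong
YFR037C	RSC8	S.par	558	2	21	frameshift	2	strong	strong
YGL058W	RAD6	S.cer	171	26	29	frameshift	2	strong	strong
YGR004W	PEX31	S.par	463	1	1	point	2	moderate	strong
YGR059W	SPR3	S.cer	512	3	9	frameshift	2	none	strong
YGR136W	LSB1	S.par	242	19	48	frameshift	2	strong	strong
YGR152C	RSR1	S.par	273	1	56	frameshift	2	strong	strong
YGR188C	BUB1	S.par	1022	3	5	frameshift	2	low	strong
YHR034C	PIH1	S.cer	341	1	1	frameshift	3	strong	strong
YHR043C	DOG2	S.cer	247	5	7	frameshift	3	strong	strong
YHR200W	RPN10	S.cer	268	18	24	frameshift	2	strong	strong
YHR206W	SKN7	S.cer	625	10	35	frameshift	2	strong	strong
YIL110W	HPM1	S.cer	378	1	4	frameshift	2	strong	strong
YIL138C	TPM2	S.cer	162	3	45	frameshift	2	strong	strong
YJL035C	TAD2	S.par	251	1	1	point	2	moderate	strong
YJL186W	MNN5	S.cer	587	21	22	frameshift	2	strong	strong
YJR075W	HOC1	S.cer	397	24	63	frameshift	2	strong	strong
YKL040C	NFU1	S.par	257	34	48	frameshift	2	strong	strong
YKL212W	SAC1	S.cer	624	5	7	frameshift	2	strong	strong
YKR006C	MRPL13	S.cer	265	3	10	frameshift	2	strong	strong
YKR069W	MET1	S.cer	591	2	2	point	2	low	strong
YLR095C	IOC2	S.cer	816	11	38	frameshift	2	strong	strong
YLR142W	PUT1	S.cer	481	5	8	frameshift	2	none	strong
YLR313C	SPH1	S.cer	650	13	13	point	2	low	strong
YLR318W	EST2	S.cer	877	2	5	frameshift	4	none	strong
YLR357W	RSC2	S.par	890	5	5	point	3	strong	strong
YLR359W	ADE13	S.cer	483	35	35	frameshift	3	strong	strong
YLR407W	NA	S.cer	229	1	4	frameshift	2	strong	strong
YML047C	PRM6	S.par	353	3	6	frameshift	2	none	strong
YMR011W	HXT2	S.par	542	6	15	frameshift	2	strong	strong
YMR240C	CUS1	S.par	437	28	41	frameshift	2	strong	strong
YNL234W	NA	S.cer	426	70	86	frameshift	2	low	moderate
YNL251C	NRD1	S.par	576	15	21	frameshift	3	strong	strong
YNL294C	RIM21	S.par	534	25	25	frameshift	2	low	strong
YOL058W	ARG1	S.cer	420	714	722	deletion_fusion	3	strong	strong
YOL086C	ADH1	S.cer	349	7	18	frameshift	2	strong	strong
YOL100W	PKH2	S.par	1082	1	10	frameshift	3	moderate	strong
YOR141C	ARP8	S.par	882	14	46	frameshift	2	strong	strong
YOR260W	GCD1	S.cer	579	11	52	frameshift	2	strong	strong
YOR387C	NA	S.cer	207	12	12	point	3	none	moderate
YPL183C	RTT10	S.cer	1014	4	7	frameshift	2	strong	strong
YPL204W	HRR25	S.cer	494	51	66	frameshift	2	strong	strong
YPL248C	GAL4	S.par	882	4	4	point	2	none	strong
YPR068C	HOS1	S.par	471	5	5	point	3	low	strong
YPR113W	PIS1	S.par	221	59	61	frameshift	2	strong	strong
YPR192W	AQY1	S.cer	306	22	34	frameshift	4	none	strong
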