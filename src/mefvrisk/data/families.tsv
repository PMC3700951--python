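# Reconstructed family table for the published case series of 63 multiplex
# FMF families (affected two-mutation proband with >=1 affected sibling).
# Only the published totals are known (69 affected siblings: 63 mm, 6 mN of
# which 3 with diagnosis not retained; 16 unaffected mN siblings); the
# per-family layout below is a synthetic reconstruction matching every total.
family_id	individual_id	role	genotype	affected	diagnosis_retained
FAM01	FAM01-1	proband	mm	1	1
FAM01	FAM01-2	sibling	mN	1	0
FAM02	FAM02-1	proband	mm	1	1
FAM02	FAM02-2	sibling	mN	1	0
FAM03	FAM03-1	proband	mm	1	1
FAM03	FAM03-2	sibling	mN	1	0
FAM04	FAM04-1	proband	mm	1	1
FAM04	FAM04-2	sibling	mN	1	1
FAM05	FAM05-1	proband	mm	1	1
FAM05	FAM05-2	sibling	mN	1	1
FAM06	FAM06-1	proband	mm	1	1
FAM06	FAM06-2	sibling	mN	1	1
FAM07	FAM07-1	proband	mm	1	1
FAM07	FAM07-2	sibling	mm	1	1
FAM07	FAM07-3	sibling	mN	0	NA
FAM08	FAM08-1	proband	mm	1	1
FAM08	FAM08-2	sibling	mm	1	1
FAM08	FAM08-3	sibling	mN	0	NA
FAM09	FAM09-1	proband	mm	1	1
FAM09	FAM09-2	sibling	mm	1	1
FAM09	FAM09-3	sibling	mN	0	NA
FAM10	FAM10-1	proband	mm	1	1
FAM10	FAM10-2	sibling	mm	1	1
FAM10	FAM10-3	sibling	mN	0	NA
FAM11	FAM11-1	proband	mm	1	1
FAM11	FAM11-2	sibling	mm	1	1
FAM11	FAM11-3	sibling	mN	0	NA
FAM12	FAM12-1	proband	mm	1	1
FAM12	FAM12-2	sibling	mm	1	1
FAM12	FAM12-3	sibling	mN	0	NA
FAM13	FAM13-1	proband	mm	1	1
FAM13	FAM13-2	sibling	mm	1	1
FAM13	FAM13-3	sibling	mN	0	NA
FAM14	FAM14-1	proband	mm	1	1
FAM14	FAM14-2	sibling	mm	1	1
FAM14	FAM14-3	sibling	mN	0	NA
FAM15	FAM15-1	proband	mm	1	1
FAM15	FAM15-2	sibling	mm	1	1
FAM15	FAM15-3	sibling	mN	0	NA
FAM16	FAM16-1	proband	mm	1	1
FAM16	FAM16-2	sibling	mm	1	1
FAM16	FAM16-3	sibling	mN	0	NA
FAM17	FAM17-1	proband	mm	1	1
FAM17	FAM17-2	sibling	mm	1	1
FAM17	FAM17-3	sibling	mN	0	NA
FAM18	FAM18-1	proband	mm	1	1
FAM18	FAM18-2	sibling	mm	1	1
FAM18	FAM18-3	sibling	mN	0	NA
FAM19	FAM19-1	proband	mm	1	1
FAM19	FAM19-2	sibling	mm	1	1
FAM19	FAM19-3	sibling	mN	0	NA
FAM20	FAM20-1	proband	mm	1	1
FAM20	FAM20-2	sibling	mm	1	1
FAM20	FAM20-3	sibling	mN	0	NA
FAM21	FAM21-1	proband	mm	1	1
FAM21	FAM21-2	sibling	mm	1	1
FAM21	FAM21-3	sibling	mN	0	NA
FAM22	FAM22-1	proband	mm	1	1
FAM22	FAM22-2	sibling	mm	1	1
FAM22	FAM22-3	sibling	mN	0	NA
FAM23	FAM23-1	proband	mm	1	1
FAM23	FAM23-2	sibling	mm	1	1
FAM24	FAM24-1	proband	mm	1	1
FAM24	FAM24-2	sibling	mm	1	1
FAM25	FAM25-1	proband	mm	1	1
FAM25	FAM25-2	sibling	mm	1	1
FAM26	FAM26-1	proband	mm	1	1
FAM26	FAM26-2	sibling	mm	1	1
FAM27	FAM27-1	proband	mm	1	1
FAM27	FAM27-2	sibling	mm	1	1
FAM28	FAM28-1	proband	mm	1	1
FAM28	FAM28-2	sibling	mm	1	1
FAM29	FAM29-1	proband	mm	1	1
FAM29	FAM29-2	sibling	mm	1	1
FAM30	FAM30-1	proband	mm	1	1
FAM30	FAM30-2	sibling	mm	1	1
FAM31	FAM31-1	proband	mm	1	1
FAM31	FAM31-2	sibling	mm	1	1
FAM32	FAM32-1	proband	mm	1	1
FAM32	FAM32-2	sibling	mm	1	1
FAM33	FAM33-1	proband	mm	1	1
FAM33	FAM33-2	sibling	mm	1	1
FAM34	FAM34-1	proband	mm	1	1
FAM34	FAM34-2	sibling	mm	1	1
FAM35	FAM35-1	proband	mm	1	1
FAM35	FAM35-2	sibling	mm	1	1
FAM36	FAM36-1	proband	mm	1	1
FAM36	FAM36-2	sibling	mm	1	1
FAM37	FAM37-1	proband	mm	1	1
FAM37	FAM37-2	sibling	mm	1	1
FAM38	FAM38-1	proband	mm	1	1
FAM38	FAM38-2	sibling	mm	1	1
FAM39	FAM39-1	proband	mm	1	1
FAM39	FAM39-2	sibling	mm	1	1
FAM40	FAM40-1	proband	mm	1	1
FAM40	FAM40-2	sibling	mm	1	1
FAM41	FAM41-1	proband	mm	1	1
FAM41	FAM41-2	sibling	mm	1	1
FAM42	FAM42-1	proband	mm	1	1
FAM42	FAM42-2	sibling	mm	1	1
FAM43	FAM43-1	proband	mm	1	1
FAM43	FAM43-2	sibling	mm	1	1
FAM44	FAM44-1	proband	mm	1	1
FAM44	FAM44-2	sibling	mm	1	1
FAM45	FAM45-1	proband	mm	1	1
FAM45	FAM45-2	sibling	mm	1	1
FAM46	FAM46-1	proband	mm	1	1
FAM46	FAM46-2	sibling	mm	1	1
FAM47	FAM47-1	proband	mm	1	1
FAM47	FAM47-2	sibling	mm	1	1
FAM48	FAM48-1	proband	mm	1	1
FAM48	FAM48-2	sibling	mm	1	1
FAM49	FAM49-1	proband	mm	1	1
FAM49	FAM49-2	sibling	mm	1	1
FAM50	FAM50-1	proband	mm	1	1
FAM50	FAM50-2	sibling	mm	1	1
FAM51	FAM51-1	proband	mm	1	1
FAM51	FAM51-2	sibling	mm	1	1
FAM52	FAM52-1	proband	mm	1	1
FAM52	FAM52-2	sibling	mm	1	1
FAM53	FAM53-1	proband	mm	1	1
FAM53	FAM53-2	sibling	mm	1	1
FAM54	FAM54-1	proband	mm	1	1
FAM54	FAM54-2	sibling	mm	1	1
FAM55	FAM55-1	proband	mm	1	1
FAM55	FAM55-2	sibling	mm	1	1
FAM56	FAM56-1	proband	mm	1	1
FAM56	FAM56-2	sibling	mm	1	1
FAM57	FAM57-1	proband	mm	1	1
FAM57	FAM57-2	sibling	mm	1	1
FAM58	FAM58-1	proband	mm	1	1
FAM58	FAM58-2	sibling	mm	1	1
FAM58	FAM58-3	sibling	mm	1	1
FAM59	FAM59-1	proband	mm	1	1
FAM59	FAM59-2	sibling	mm	1	1
FAM59	FAM59-3	sibling	mm	1	1
FAM60	FAM60-1	proband	mm	1	1
FAM60	FAM60-2	sibling	mm	1	1
FAM60	FAM60-3	sibling	mm	1	1
FAM61	FAM61-1	proband	mm	1	1
FAM61	FAM61-2	sibling	mm	1	1
FAM61	FAM61-3	sibling	mm	1	1
FAM62	FAM62-1	proband	mm	1	1
FAM62	FAM62-2	sibling	mm	1	1
FAM62	FAM62-3	sibling	mm	1	1
FAM63	FAM63-1	proband	mm	1	1
FAM63	FAM63-2	sibling	mm	1	1
FAM63	FAM63-3	sibling	mm	1	1
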