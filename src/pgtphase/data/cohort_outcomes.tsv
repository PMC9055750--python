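# per-family PGT outcomes of the 36-couple thalassemia cohort
# columns:
#   family             family identifier (1-36)
#   pgt_cycles         oocyte pick-up / PGT cycles performed
#   fet_cycles         frozen embryo transfer cycles performed
#   oocytes            oocytes retrieved
#   mii                mature (MII) oocytes injected by ICSI
#   fertilized_2pn     normally fertilized (2PN) zygotes
#   cleavage           cleavage-stage embryos
#   blastocysts        blastocysts formed
#   biopsied           blastocysts of biopsy-grade quality that were biopsied
#   unaffected         biopsied embryos diagnosed carrier or noncarrier
#   transferable       unaffected AND euploid embryos
#   clinical_pregnancy FET cycles reaching clinical pregnancy
#   live_birth         babies live-born (family 15: twins from one transfer)
#   pgt_m_result       monogenic status of the transferred embryo(s)
#   amniocentesis      prenatal confirmation result (NA if not done)
#   after_born         postnatal confirmation result (NA if not done)
#   note               row-level caveats ('.' = none)
# family 27's digits are ambiguous in the available transcription; its row
# is reconstructed from the column totals, all of which match the cohort's
# reported aggregates exactly.
family	pgt_cycles	fet_cycles	oocytes	mii	fertilized_2pn	cleavage	blastocysts	biopsied	unaffected	transferable	clinical_pregnancy	live_birth	pgt_m_result	amniocentesis	after_born	note
1	1	1	26	25	18	17	12	9	6	3	1	1	Wild type	Wild type	Wild type	.
2	1	1	22	17	15	15	8	8	6	4	1	1	Heterozygote	Heterozygote	Heterozygote	.
3	1	1	13	12	10	10	6	3	2	1	1	1	Wild type	NA	Wild type	.
4	1	1	11	10	9	9	7	5	2	2	1	1	Wild type	NA	Wild type	.
5	1	1	12	12	11	11	11	9	6	3	1	1	Heterozygote	Heterozygote	Heterozygote	.
6	1	2	15	14	12	11	10	7	6	2	1	1	Heterozygote	Heterozygote	Heterozygote	.
7	1	1	24	20	15	14	8	4	4	1	1	1	Heterozygote	Heterozygote	Heterozygote	.
8	2	2	44	31	21	21	15	8	6	4	1	1	Heterozygote	NA	Heterozygote	second_oocyte_pickup
9	1	2	35	27	21	21	16	6	6	6	1	0	Wild type	Miscarriage	NA	.
10	1	1	28	16	11	11	7	4	1	1	1	0	Wild type	Miscarriage	NA	.
11	1	1	15	11	10	10	6	5	3	2	1	1	Wild type	Wild type	NA	.
12	1	3	21	16	13	13	7	4	4	3	1	1	Heterozygote	NA	Heterozygote	.
13	1	2	26	20	16	16	13	9	7	5	1	1	Wild type	Wild type	NA	.
14	1	2	7	5	4	4	3	3	1	1	0	0	Heterozygote	NA	NA	.
15	2	1	48	36	29	29	23	11	7	2	1	2	Wild type	NA	Wild type	single_transfer_monochorionic_diamniotic_twins
16	1	1	19	12	9	9	7	4	3	2	1	1	Heterozygote	Heterozygote	NA	.
17	1	0	6	4	3	3	3	2	0	0	0	0	NA	NA	NA	.
18	1	1	19	10	4	4	4	3	2	2	1	1	Heterozygote	Heterozygote	NA	.
19	1	3	40	33	27	27	24	15	11	11	1	1	Heterozygote	NA	Heterozygote	.
20	1	2	25	21	13	12	10	4	4	3	1	1	Heterozygote	NA	Heterozygote	.
21	1	1	19	14	13	13	9	8	8	4	1	1	Wild type	Wild type	NA	.
22	1	1	19	13	10	10	8	5	5	3	1	1	Heterozygote	Heterozygote	NA	.
23	1	1	29	27	25	25	19	6	4	4	1	0	Heterozygote	NA	NA	.
24	1	1	16	15	15	14	10	7	4	4	1	1	Heterozygote	Heterozygote	NA	.
25	1	1	19	19	19	18	8	5	3	2	1	0	Wild type	Miscarriage	NA	.
26	1	2	8	7	4	4	4	4	4	4	1	0	Wild type	Miscarriage	NA	.
27	1	2	11	9	8	8	8	8	5	3	1	0	Wild type	Miscarriage	NA	row_digits_ambiguous_in_source
28	1	1	11	11	7	7	3	3	2	1	0	0	Wild type	NA	NA	.
29	1	2	17	13	8	8	8	5	3	3	0	0	Wild type	NA	NA	.
30	2	4	47	40	33	33	16	10	7	6	2	0	Wild type	Miscarriage	NA	.
31	2	3	27	26	14	14	8	7	6	5	1	1	Heterozygote	Heterozygote	Heterozygote	second_oocyte_pickup
32	1	2	21	15	13	13	11	6	5	5	1	1	Heterozygote	Heterozygote	Heterozygote	.
33	1	0	15	14	12	12	3	3	1	0	0	0	NA	NA	NA	.
34	1	1	12	11	11	11	9	7	7	7	1	1	Wild type	NA	Wild type	.
35	2	1	28	28	20	20	9	4	4	1	1	0	Heterozygote	Heterozygote	NA	second_oocyte_pickup
36	1	1	22	17	16	15	8	6	5	2	1	0	Heterozygote	Heterozygote	NA	.
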