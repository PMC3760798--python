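# Dissociation constants and thermodynamic parameters from ITC titrations of
# RelA TAD peptides into CBP-TAZ1 at 25 °C (quantified rows only; the F473A
# construct showed no measurable binding and is omitted).
# Columns: Kd in nM, ΔH and TΔS in kcal/mol, NaCl in mM.
label	salt_mM	kd_nM	kd_err	dh_kcal	dh_err	tds_kcal	tds_err
wt_425-508	50	57.0	3.2	-5.9	0.1	3.9	0.1
S467D_425-508	50	41.2	0.3	-6.5	0.1	3.5	0.1
wt_425-508	150	244.4	11.3	-7.2	0.1	1.8	0.1
wt_441-508	150	386.8	33.4	-8.3	0.4	0.5	0.5
L449A_425-508	150	1604.5	194.1	-5.4	0.3	2.5	0.3
L465A_425-508	150	1706.8	434.5	-2.4	0.3	5.5	0.5
S467D_425-508	150	173.9	7.2	-7.8	0.1	1.4	0.1
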