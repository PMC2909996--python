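# Nearest-neighbor duplex parameters, version 1.
# Watson-Crick stacks and initiation: SantaLucia (1998) unified set.
# Internal mismatches: Allawi & SantaLucia (1997-1998), Peyret et al. (1999).
# Terminal mismatches: SantaLucia & Hicks (2004) compilation.
# Stack notation XY/WZ: top strand 5'-XY-3' paired with bottom strand 3'-WZ-5'.
kind	stack	dh_kcal_mol	ds_cal_mol_K
wc	AA/TT	-7.9	-22.2
wc	AT/TA	-7.2	-20.4
wc	CA/GT	-8.5	-22.7
wc	CG/GC	-10.6	-27.2
wc	CT/GA	-7.8	-21.0
wc	GA/CT	-8.2	-22.2
wc	GC/CG	-9.8	-24.4
wc	GG/CC	-8.0	-19.9
wc	GT/CA	-8.4	-22.4
wc	TA/AT	-7.2	-21.3
init	init	0	0
init	init_5T/A	0	0
init	init_A/T	2.3	4.1
init	init_G/C	0.1	-2.8
init	init_allA/T	0	0
init	init_oneG/C	0	0
init	sym	0	-1.4
imm	AA/TA	1.2	1.7
imm	AA/TC	2.3	4.6
imm	AA/TG	-0.6	-2.3
imm	AA/TI	-0.7	-2.6
imm	AC/TA	5.3	14.6
imm	AC/TC	0.0	-4.4
imm	AC/TI	-8.8	-25.4
imm	AC/TT	0.7	0.2
imm	AG/TA	-0.7	-2.3
imm	AG/TG	-3.1	-9.5
imm	AG/TI	0.1	-1.8
imm	AG/TT	1.0	0.9
imm	AI/TA	-8.3	-25.0
imm	AI/TC	-8.9	-25.5
imm	AI/TG	-4.9	-15.8
imm	AI/TI	-3.3	-11.9
imm	AI/TT	0.49	-0.7
imm	AT/TC	-1.2	-6.2
imm	AT/TG	-2.5	-8.3
imm	AT/TI	-5.6	-18.7
imm	AT/TT	-2.7	-10.8
imm	CA/GA	-0.9	-4.2
imm	CA/GC	1.9	3.7
imm	CA/GG	-0.7	-2.3
imm	CA/GI	-7.0	-20.0
imm	CC/GA	0.6	-0.6
imm	CC/GC	-1.5	-7.2
imm	CC/GI	-8.3	-23.8
imm	CC/GT	-0.8	-4.5
imm	CG/GA	-4.0	-13.2
imm	CG/GG	-4.9	-15.3
imm	CG/GI	5.8	16.9
imm	CG/GT	-4.1	-11.7
imm	CI/GA	2.6	8.9
imm	CI/GC	-5.4	-13.7
imm	CI/GG	7.1	21.3
imm	CI/GI	1.3	3.0
imm	CI/GT	-1.0	-2.4
imm	CT/GC	-1.5	-6.1
imm	CT/GG	-2.8	-8.0
imm	CT/GI	0.1	-1.0
imm	CT/GT	-5.0	-15.8
imm	GA/CA	-2.9	-9.8
imm	GA/CC	5.2	14.2
imm	GA/CG	-0.6	-1.0
imm	GA/CI	-7.6	-20.2
imm	GC/CA	-0.7	-3.8
imm	GC/CC	3.6	8.9
imm	GC/CI	-5.0	-12.6
imm	GC/CT	2.3	5.4
imm	GG/CA	0.5	3.2
imm	GG/CG	-6.0	-15.8
imm	GG/CI	-7.6	-22.0
imm	GG/CT	3.3	10.4
imm	GG/TT	5.8	16.3
imm	GI/CA	-7.8	-21.1
imm	GI/CC	-6.8	-19.1
imm	GI/CG	-1.1	-3.2
imm	GI/CI	-0.5	-1.3
imm	GI/CT	-3.5	-10.6
imm	GT/CC	5.2	13.5
imm	GT/CG	-4.4	-12.3
imm	GT/CI	-4.3	-12.1
imm	GT/CT	-2.2	-8.4
imm	GT/TG	4.1	9.5
imm	TA/AA	4.7	12.9
imm	TA/AC	3.4	8.0
imm	TA/AG	0.7	0.7
imm	TA/AI	-1.3	-4.6
imm	TC/AA	7.6	20.2
imm	TC/AC	6.1	16.4
imm	TC/AI	-4.9	-13.9
imm	TC/AT	1.2	0.7
imm	TG/AA	3.0	7.4
imm	TG/AG	1.6	3.6
imm	TG/AI	1.0	1.0
imm	TG/AT	-0.1	-1.7
imm	TG/GT	-1.4	-6.2
imm	TI/AA	-3.4	-11.2
imm	TI/AC	-5.9	-17.4
imm	TI/AG	-1.9	-8.5
imm	TI/AI	0.1	-2.3
imm	TI/AT	-6.5	-22.0
imm	TT/AC	1.0	0.7
imm	TT/AG	-1.3	-5.3
imm	TT/AI	-0.8	-4.3
imm	TT/AT	0.2	-1.5
tmm	AA/TA	-3.1	-7.8
tmm	AA/TC	-1.6	-4.0
tmm	AA/TG	-1.9	-4.4
tmm	AC/TA	-1.8	-3.8
tmm	AC/TC	-0.1	0.5
tmm	AC/TT	-0.9	-1.7
tmm	AG/TA	-2.5	-5.9
tmm	AG/TG	-1.1	-2.1
tmm	AG/TT	-3.2	-8.7
tmm	AT/TC	-2.3	-6.3
tmm	AT/TG	-3.5	-9.4
tmm	AT/TT	-2.4	-6.5
tmm	CA/GA	-4.3	-10.7
tmm	CA/GC	-2.6	-5.9
tmm	CA/GG	-3.9	-9.6
tmm	CC/GA	-2.7	-6.0
tmm	CC/GC	-2.1	-5.1
tmm	CC/GT	-3.2	-8.0
tmm	CG/GA	-6.0	-15.5
tmm	CG/GG	-3.8	-9.5
tmm	CG/GT	-3.8	-9.0
tmm	CT/GC	-3.9	-10.6
tmm	CT/GG	-6.6	-18.7
tmm	CT/GT	-6.1	-16.9
tmm	GA/CA	-8.0	-22.5
tmm	GA/CC	-5.0	-13.8
tmm	GA/CG	-4.3	-11.1
tmm	GC/CA	-3.2	-7.1
tmm	GC/CC	-3.9	-10.6
tmm	GC/CT	-4.9	-13.5
tmm	GG/CA	-4.6	-11.4
tmm	GG/CG	-0.7	-19.2
tmm	GG/CT	-5.7	-15.9
tmm	GT/CC	-3.0	-7.8
tmm	GT/CG	-5.9	-16.1
tmm	GT/CT	-7.4	-21.2
tmm	TA/AA	-2.5	-6.3
tmm	TA/AC	-2.3	-5.9
tmm	TA/AG	-2.0	-4.7
tmm	TC/AA	-2.7	-7.0
tmm	TC/AC	-0.7	-1.3
tmm	TC/AT	-2.5	-6.3
tmm	TG/AA	-2.4	-5.8
tmm	TG/AG	-1.1	-2.7
tmm	TG/AT	-3.9	-10.5
tmm	TT/AC	-0.7	-1.2
tmm	TT/AG	-3.6	-9.8
tmm	TT/AT	-3.2	-8.9
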