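# 1H chemical signature of Macrotyloma uniflorum (horsegram) seed extracts, 600 MHz,
# CD3OD/D2O 80:20, referenced to TSP at 0.00 ppm.
# Columns:
#   name              snake_case identifier (unique)
#   metabolite_class  amino_acid | sugar | flavonoid_polyphenol |
#                     organic_phenolic_steroid_sugar_alcohol | vitamin |
#                     internal_standard
#   shifts_ppm        characteristic shifts, ';'-separated; first is the
#                     quantification signal
#   multiplicities    one of s,d,dd,t,m per shift, ';'-separated
#   quant_shift_ppm   shift whose integral enters the qNMR mass formula
#   n_protons         protons behind the quantification signal (assigned group)
#   molecular_weight  average MW, g/mol (free compound unless noted)
#   source            shift provenance: text | supplement | inferred
#   note              assigned group / caveats
name	metabolite_class	shifts_ppm	multiplicities	quant_shift_ppm	n_protons	molecular_weight	source	note
isoleucine	amino_acid	0.88	d	0.88	3	131.17	text	delta-CH3
leucine	amino_acid	0.97	d	0.97	6	131.17	text	two overlapping CH3 doublets
valine	amino_acid	1.06	d	1.06	3	117.15	text	gamma-CH3
threonine	amino_acid	1.32	d	1.32	3	119.12	text	gamma-CH3
alanine	amino_acid	1.466	d	1.466	3	89.09	text	beta-CH3
arginine	amino_acid	1.68	m	1.68	2	174.20	supplement	gamma-CH2; identity imputed, see docs
quinic_acid	organic_phenolic_steroid_sugar_alcohol	1.83;1.96	d;d	1.83	2	192.17	text	ring CH2
glutamine	amino_acid	2.04	m	2.04	2	146.14	text	beta-CH2
methionine	amino_acid	2.14	s	2.14	3	149.21	text	S-CH3
malic_acid	organic_phenolic_steroid_sugar_alcohol	2.37	dd	2.37	1	134.09	text	CH2(a)
succinic_acid	organic_phenolic_steroid_sugar_alcohol	2.542	s	2.542	4	118.09	text	2x CH2
asparagine	amino_acid	2.85	m	2.85	2	132.12	text	beta-CH2
lysine	amino_acid	3.03	t	3.03	2	146.19	text	epsilon-CH2
choline	organic_phenolic_steroid_sugar_alcohol	3.23;3.27	s;s	3.23	9	104.17	text	N(CH3)3 cation
inositol	organic_phenolic_steroid_sugar_alcohol	3.49	dd	3.49	2	180.16	text	H1/H3
glycine	amino_acid	3.57	s	3.57	2	75.07	text	alpha-CH2
glutamic_acid	amino_acid	3.74	dd	3.74	1	147.13	text	alpha-CH
maltose	sugar	3.88	dd	3.88	1	342.30	text
serine	amino_acid	3.95	m	3.95	2	105.09	text	beta-CH2 (3.9440-3.9520)
fructose	sugar	4.06	d	4.06	1	180.16	text
cystine	amino_acid	4.13	dd	4.13	1	240.30	text	alpha-CH
beta_glucose	sugar	4.57	d	4.57	1	180.16	text	anomeric H
alpha_glucose	sugar	5.13	d	5.13	1	180.16	text	anomeric H
d_xylose	sugar	5.22	d	5.22	1	150.13	text	anomeric H
alpha_galactose	sugar	5.25	d	5.25	1	180.16	text	anomeric H
chlorogenic_acid	organic_phenolic_steroid_sugar_alcohol	5.35	m	5.35	1	354.31	text	quinic H-5
sucrose_stachyose	sugar	5.42	d	5.42	1	342.30	text	anomeric H; sucrose MW used
quercetin_conjugates	flavonoid_polyphenol	6.20;6.21	d;d	6.20	1	464.38	text	quercetin-3-O-glucoside MW
rutin	flavonoid_polyphenol	6.39	d	6.39	1	610.52	text	H-8
apigenin_derivatives	flavonoid_polyphenol	6.51;6.579;6.656;6.8561	d;s;s;s	6.51	1	432.38	text	apigenin-7-O-glucoside MW
caffeic_acid	organic_phenolic_steroid_sugar_alcohol	6.88	d	6.88	1	180.16	text
protocatechuic_acid	organic_phenolic_steroid_sugar_alcohol	6.91	d	6.91	1	154.12	text
gallic_acid	organic_phenolic_steroid_sugar_alcohol	6.99	s	6.99	2	170.12	text	2 aromatic H
kaempferol_glycoside	flavonoid_polyphenol	7.15	d	7.15	2	448.38	text	H-2'/H-6'; kaempferol-3-O-glucoside MW
myricetin	flavonoid_polyphenol	7.25	s	7.25	2	318.23	text	H-2'/H-6'
riboflavin	vitamin	7.31	s	7.31	1	376.36	text	aromatic H
phenylalanine	amino_acid	7.4176	m	7.4176	3	165.19	text	ring H (7.4104-7.4176)
quercetin	flavonoid_polyphenol	7.59	d	7.59	1	302.24	text	H-6'
quercetin_3_o_galactoside	flavonoid_polyphenol	7.69	d	7.69	1	464.38	text	H-6'
tryptophan	amino_acid	7.72	d	7.72	1	204.23	text	indole H-4
histidine	amino_acid	7.89	s	7.89	1	155.15	text	imidazole H-2
thiamine	vitamin	8.04	s	8.04	1	265.35	text	aromatic H; cation MW
niacin	vitamin	8.80	dd	8.80	1	123.11	text	pyridine H-2
stigmasterol	organic_phenolic_steroid_sugar_alcohol	1.04	s	1.04	3	412.69	text	C-19 CH3
tocopherol	vitamin	1.24	s	1.24	3	430.71	inferred	chroman CH3; shift imputed, see docs
tsp	internal_standard	0.00	s	0.00	9	196.36	text	Si(CH3)3; 3-(trimethylsilyl)-1-propanesulfonic acid
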