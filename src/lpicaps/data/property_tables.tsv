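# Residue property tables used for the physicochemical feature channel.
# Columns: table<TAB>target<TAB>residue<TAB>value
#
# RNA (2 tables): per-base hydrogen-bonding capacity (number of Watson-
# Crick hydrogen bonds the base can form) and a van der Waals contact
# scale (heavy-atom count of the base, a standard surrogate for dispersion
# interaction surface).  Protein (8 tables, AAindex accessions noted):
# Bull & Breese hydrophobicity (BULH740101), Kyte & Doolittle
# hydropathy (KYTJ820101), Zimmerman polarity (ZIMJ680103), Grantham
# polarity (GRAR740102), isoelectric point (ZIMJ680104), bulkiness
# (ZIMJ680102), Eisenberg consensus hydrophobicity (EISD840101), and
# Hopp & Woods hydrophilicity (HOPT810101).  Values follow each source
# scale; the tables are editable configuration, not fixed contracts.
vdw	rna	A	10
vdw	rna	C	8
vdw	rna	G	11
vdw	rna	U	8
hbond	rna	A	2
hbond	rna	C	3
hbond	rna	G	3
hbond	rna	U	2
bull_breese	protein	A	0.61
bull_breese	protein	R	0.69
bull_breese	protein	N	0.89
bull_breese	protein	D	0.61
bull_breese	protein	C	0.36
bull_breese	protein	Q	0.97
bull_breese	protein	E	0.51
bull_breese	protein	G	0.81
bull_breese	protein	H	0.69
bull_breese	protein	I	-1.45
bull_breese	protein	L	-1.65
bull_breese	protein	K	0.46
bull_breese	protein	M	-0.66
bull_breese	protein	F	-1.52
bull_breese	protein	P	-0.17
bull_breese	protein	S	0.42
bull_breese	protein	T	0.29
bull_breese	protein	W	-1.20
bull_breese	protein	Y	-1.43
bull_breese	protein	V	-0.75
kyte_doolittle	protein	A	1.8
kyte_doolittle	protein	R	-4.5
kyte_doolittle	protein	N	-3.5
kyte_doolittle	protein	D	-3.5
kyte_doolittle	protein	C	2.5
kyte_doolittle	protein	Q	-3.5
kyte_doolittle	protein	E	-3.5
kyte_doolittle	protein	G	-0.4
kyte_doolittle	protein	H	-3.2
kyte_doolittle	protein	I	4.5
kyte_doolittle	protein	L	3.8
kyte_doolittle	protein	K	-3.9
kyte_doolittle	protein	M	1.9
kyte_doolittle	protein	F	2.8
kyte_doolittle	protein	P	-1.6
kyte_doolittle	protein	S	-0.8
kyte_doolittle	protein	T	-0.7
kyte_doolittle	protein	W	-0.9
kyte_doolittle	protein	Y	-1.3
kyte_doolittle	protein	V	4.2
zimmerman_polarity	protein	A	0.00
zimmerman_polarity	protein	R	52.00
zimmerman_polarity	protein	N	3.38
zimmerman_polarity	protein	D	49.70
zimmerman_polarity	protein	C	1.48
zimmerman_polarity	protein	Q	3.53
zimmerman_polarity	protein	E	49.90
zimmerman_polarity	protein	G	0.00
zimmerman_polarity	protein	H	51.60
zimmerman_polarity	protein	I	0.13
zimmerman_polarity	protein	L	0.13
zimmerman_polarity	protein	K	49.50
zimmerman_polarity	protein	M	1.43
zimmerman_polarity	protein	F	0.35
zimmerman_polarity	protein	P	1.58
zimmerman_polarity	protein	S	1.67
zimmerman_polarity	protein	T	1.66
zimmerman_polarity	protein	W	2.10
zimmerman_polarity	protein	Y	1.61
zimmerman_polarity	protein	V	0.13
grantham_polarity	protein	A	8.1
grantham_polarity	protein	R	10.5
grantham_polarity	protein	N	11.6
grantham_polarity	protein	D	13.0
grantham_polarity	protein	C	5.5
grantham_polarity	protein	Q	10.5
grantham_polarity	protein	E	12.3
grantham_polarity	protein	G	9.0
grantham_polarity	protein	H	10.4
grantham_polarity	protein	I	5.2
grantham_polarity	protein	L	4.9
grantham_polarity	protein	K	11.3
grantham_polarity	protein	M	5.7
grantham_polarity	protein	F	5.2
grantham_polarity	protein	P	8.0
grantham_polarity	protein	S	9.2
grantham_polarity	protein	T	8.6
grantham_polarity	protein	W	5.4
grantham_polarity	protein	Y	6.2
grantham_polarity	protein	V	5.9
isoelectric_point	protein	A	6.00
isoelectric_point	protein	R	10.76
isoelectric_point	protein	N	5.41
isoelectric_point	protein	D	2.77
isoelectric_point	protein	C	5.05
isoelectric_point	protein	Q	5.65
isoelectric_point	protein	E	3.22
isoelectric_point	protein	G	5.97
isoelectric_point	protein	H	7.59
isoelectric_point	protein	I	6.02
isoelectric_point	protein	L	5.98
isoelectric_point	protein	K	9.74
isoelectric_point	protein	M	5.74
isoelectric_point	protein	F	5.48
isoelectric_point	protein	P	6.30
isoelectric_point	protein	S	5.68
isoelectric_point	protein	T	5.66
isoelectric_point	protein	W	5.89
isoelectric_point	protein	Y	5.66
isoelectric_point	protein	V	5.96
bulkiness	protein	A	11.50
bulkiness	protein	R	14.28
bulkiness	protein	N	12.82
bulkiness	protein	D	11.68
bulkiness	protein	C	13.46
bulkiness	protein	Q	14.45
bulkiness	protein	E	13.57
bulkiness	protein	G	3.40
bulkiness	protein	H	13.69
bulkiness	protein	I	21.40
bulkiness	protein	L	21.40
bulkiness	protein	K	15.71
bulkiness	protein	M	16.25
bulkiness	protein	F	19.80
bulkiness	protein	P	17.43
bulkiness	protein	S	9.47
bulkiness	protein	T	15.77
bulkiness	protein	W	21.67
bulkiness	protein	Y	18.03
bulkiness	protein	V	21.57
eisenberg	protein	A	0.62
eisenberg	protein	R	-2.53
eisenberg	protein	N	-0.78
eisenberg	protein	D	-0.90
eisenberg	protein	C	0.29
eisenberg	protein	Q	-0.85
eisenberg	protein	E	-0.74
eisenberg	protein	G	0.48
eisenberg	protein	H	-0.40
eisenberg	protein	I	1.38
eisenberg	protein	L	1.06
eisenberg	protein	K	-1.50
eisenberg	protein	M	0.64
eisenberg	protein	F	1.19
eisenberg	protein	P	0.12
eisenberg	protein	S	-0.18
eisenberg	protein	T	-0.05
eisenberg	protein	W	0.81
eisenberg	protein	Y	0.26
eisenberg	protein	V	1.08
hopp_woods	protein	A	-0.5
hopp_woods	protein	R	3.0
hopp_woods	protein	N	0.2
hopp_woods	protein	D	3.0
hopp_woods	protein	C	-1.0
hopp_woods	protein	Q	0.2
hopp_woods	protein	E	3.0
hopp_woods	protein	G	0.0
hopp_woods	protein	H	-0.5
hopp_woods	protein	I	-1.8
hopp_woods	protein	L	-1.8
hopp_woods	protein	K	3.0
hopp_woods	protein	M	-1.3
hopp_woods	protein	F	-2.5
hopp_woods	protein	P	0.0
hopp_woods	protein	S	0.3
hopp_woods	protein	T	-0.4
hopp_woods	protein	W	-3.4
hopp_woods	protein	Y	-2.3
hopp_woods	protein	V	-1.5
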