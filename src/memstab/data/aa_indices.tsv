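# Curated per-residue physicochemical indices (AAindex-style).
# kd_hydropathy: Kyte & Doolittle (1982) hydropathy.
# volume: Zamyatnin (1972) residue volume, cubic Angstrom.
# polarity: Grantham (1974) polarity.
# flexibility: Bhaskaran & Ponnuswamy (1988) average flexibility.
aa	kd_hydropathy	volume	polarity	flexibility
A	1.8	88.6	8.1	0.357
R	-4.5	173.4	10.5	0.529
N	-3.5	114.1	11.6	0.463
D	-3.5	111.1	13.0	0.511
C	2.5	108.5	5.5	0.346
Q	-3.5	143.8	10.5	0.493
E	-3.5	138.4	12.3	0.497
G	-0.4	60.1	9.0	0.544
H	-3.2	153.2	10.4	0.323
I	4.5	166.7	5.2	0.462
L	3.8	166.7	4.9	0.365
K	-3.9	168.6	11.3	0.466
M	1.9	162.9	5.7	0.295
F	2.8	189.9	5.2	0.314
P	-1.6	112.7	8.0	0.509
S	-0.8	89.0	9.2	0.507
T	-0.7	116.1	8.6	0.444
W	-0.9	227.8	5.4	0.305
Y	-1.3	193.6	6.2	0.420
V	4.2	140.0	5.9	0.386
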