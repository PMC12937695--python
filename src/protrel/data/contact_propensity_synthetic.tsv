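# Synthetic contact-propensity matrix: w(x,y) = (h_x + h_y) / 9.0,
# where h is the Kyte-Doolittle hydropathy index. Symmetric, 20x20.
	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
A	0.4000	-0.3000	-0.1889	-0.1889	0.4778	-0.1889	-0.1889	0.1556	-0.1556	0.7000	0.6222	-0.2333	0.4111	0.5111	0.0222	0.1111	0.1222	0.1000	0.0556	0.6667
R	-0.3000	-1.0000	-0.8889	-0.8889	-0.2222	-0.8889	-0.8889	-0.5444	-0.8556	0.0000	-0.0778	-0.9333	-0.2889	-0.1889	-0.6778	-0.5889	-0.5778	-0.6000	-0.6444	-0.0333
N	-0.1889	-0.8889	-0.7778	-0.7778	-0.1111	-0.7778	-0.7778	-0.4333	-0.7444	0.1111	0.0333	-0.8222	-0.1778	-0.0778	-0.5667	-0.4778	-0.4667	-0.4889	-0.5333	0.0778
D	-0.1889	-0.8889	-0.7778	-0.7778	-0.1111	-0.7778	-0.7778	-0.4333	-0.7444	0.1111	0.0333	-0.8222	-0.1778	-0.0778	-0.5667	-0.4778	-0.4667	-0.4889	-0.5333	0.0778
C	0.4778	-0.2222	-0.1111	-0.1111	0.5556	-0.1111	-0.1111	0.2333	-0.0778	0.7778	0.7000	-0.1556	0.4889	0.5889	0.1000	0.1889	0.2000	0.1778	0.1333	0.7444
Q	-0.1889	-0.8889	-0.7778	-0.7778	-0.1111	-0.7778	-0.7778	-0.4333	-0.7444	0.1111	0.0333	-0.8222	-0.1778	-0.0778	-0.5667	-0.4778	-0.4667	-0.4889	-0.5333	0.0778
E	-0.1889	-0.8889	-0.7778	-0.7778	-0.1111	-0.7778	-0.7778	-0.4333	-0.7444	0.1111	0.0333	-0.8222	-0.1778	-0.0778	-0.5667	-0.4778	-0.4667	-0.4889	-0.5333	0.0778
G	0.1556	-0.5444	-0.4333	-0.4333	0.2333	-0.4333	-0.4333	-0.0889	-0.4000	0.4556	0.3778	-0.4778	0.1667	0.2667	-0.2222	-0.1333	-0.1222	-0.1444	-0.1889	0.4222
H	-0.1556	-0.8556	-0.7444	-0.7444	-0.0778	-0.7444	-0.7444	-0.4000	-0.7111	0.1444	0.0667	-0.7889	-0.1444	-0.0444	-0.5333	-0.4444	-0.4333	-0.4556	-0.5000	0.1111
I	0.7000	0.0000	0.1111	0.1111	0.7778	0.1111	0.1111	0.4556	0.1444	1.0000	0.9222	0.0667	0.7111	0.8111	0.3222	0.4111	0.4222	0.4000	0.3556	0.9667
L	0.6222	-0.0778	0.0333	0.0333	0.7000	0.0333	0.0333	0.3778	0.0667	0.9222	0.8444	-0.0111	0.6333	0.7333	0.2444	0.3333	0.3444	0.3222	0.2778	0.8889
K	-0.2333	-0.9333	-0.8222	-0.8222	-0.1556	-0.8222	-0.8222	-0.4778	-0.7889	0.0667	-0.0111	-0.8667	-0.2222	-0.1222	-0.6111	-0.5222	-0.5111	-0.5333	-0.5778	0.0333
M	0.4111	-0.2889	-0.1778	-0.1778	0.4889	-0.1778	-0.1778	0.1667	-0.1444	0.7111	0.6333	-0.2222	0.4222	0.5222	0.0333	0.1222	0.1333	0.1111	0.0667	0.6778
F	0.5111	-0.1889	-0.0778	-0.0778	0.5889	-0.0778	-0.0778	0.2667	-0.0444	0.8111	0.7333	-0.1222	0.5222	0.6222	0.1333	0.2222	0.2333	0.2111	0.1667	0.7778
P	0.0222	-0.6778	-0.5667	-0.5667	0.1000	-0.5667	-0.5667	-0.2222	-0.5333	0.3222	0.2444	-0.6111	0.0333	0.1333	-0.3556	-0.2667	-0.2556	-0.2778	-0.3222	0.2889
S	0.1111	-0.5889	-0.4778	-0.4778	0.1889	-0.4778	-0.4778	-0.1333	-0.4444	0.4111	0.3333	-0.5222	0.1222	0.2222	-0.2667	-0.1778	-0.1667	-0.1889	-0.2333	0.3778
T	0.1222	-0.5778	-0.4667	-0.4667	0.2000	-0.4667	-0.4667	-0.1222	-0.4333	0.4222	0.3444	-0.5111	0.1333	0.2333	-0.2556	-0.1667	-0.1556	-0.1778	-0.2222	0.3889
W	0.1000	-0.6000	-0.4889	-0.4889	0.1778	-0.4889	-0.4889	-0.1444	-0.4556	0.4000	0.3222	-0.5333	0.1111	0.2111	-0.2778	-0.1889	-0.1778	-0.2000	-0.2444	0.3667
Y	0.0556	-0.6444	-0.5333	-0.5333	0.1333	-0.5333	-0.5333	-0.1889	-0.5000	0.3556	0.2778	-0.5778	0.0667	0.1667	-0.3222	-0.2333	-0.2222	-0.2444	-0.2889	0.3222
V	0.6667	-0.0333	0.0778	0.0778	0.7444	0.0778	0.0778	0.4222	0.1111	0.9667	0.8889	0.0333	0.6778	0.7778	0.2889	0.3778	0.3889	0.3667	0.3222	0.9333
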