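# amino-acid residue formulas and monoisotopic masses, Da (table version 1)
# L and I are isobaric; CID cannot distinguish them
symbol	formula	mass
G	C2H3NO	57.0214637
A	C3H5NO	71.0371138
S	C3H5NO2	87.0320284
P	C5H7NO	97.0527639
V	C5H9NO	99.0684139
T	C4H7NO2	101.0476785
L	C6H11NO	113.0840640
I	C6H11NO	113.0840640
N	C4H6N2O2	114.0429274
D	C4H5NO3	115.0269430
Q	C5H8N2O2	128.0585775
K	C6H12N2O	128.0949630
E	C5H7NO3	129.0425931
M	C5H9NOS	131.0404846
H	C6H7N3O	137.0589119
F	C9H9NO	147.0684139
R	C6H12N4O	156.1011110
Y	C9H9NO2	163.0633285
W	C11H10N2O	186.0793130
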