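# Per-residue parameters of the dynamic-contact force field.
# radius_nm: sidechain contact radius; the ss Lennard-Jones minimum for a
#   pair (i, j) sits at radius_i + radius_j.  Values are size-graded
#   surrogates for the unpublished pair table of the parent model and are
#   meant to be edited for quantitative parity with it.
# bb_slots / sc_slots: maximum simultaneous dynamic contacts the virtual
#   backbone and sidechain of the residue can hold.
# charge: net charge in elementary units (implicit-solvent convention:
#   Lys/Arg +1, Asp/Glu -1, His neutral).
residue	radius_nm	bb_slots	sc_slots	charge
G	0.25	2	0	0
A	0.27	2	1	0
S	0.27	2	2	0
C	0.30	2	2	0
T	0.29	2	2	0
P	0.30	2	1	0
V	0.31	2	1	0
D	0.30	2	2	-1
N	0.31	2	2	0
L	0.33	2	1	0
I	0.33	2	1	0
E	0.32	2	2	-1
Q	0.33	2	2	0
M	0.34	2	1	0
K	0.34	2	2	1
H	0.34	2	2	0
F	0.36	2	2	0
R	0.36	2	3	1
Y	0.37	2	3	0
W	0.39	2	3	0
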