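# Synthetic per-atom parameter table for the toy systems (NOT a force field).
# Charges sum to zero within every residue type so net system charge is an
# integer by construction.  Units: charge e, sigma Å, epsilon kJ/mol,
# f (lipophilicity) dimensionless, vdw radius Å.
# residue	atom	element	charge	sigma	epsilon	f	vdw	aromatic
ARO	N	N	-0.40	3.25	0.71	-0.50	1.55	0
ARO	CA	C	0.10	3.40	0.36	0.05	1.70	0
ARO	C	C	0.50	3.40	0.36	-0.10	1.70	0
ARO	O	O	-0.50	2.96	0.88	-0.40	1.52	0
ARO	CB	C	0.30	3.55	0.29	0.70	1.77	1
APO	N	N	-0.30	3.25	0.71	-0.50	1.55	0
APO	CA	C	0.20	3.40	0.36	0.05	1.70	0
APO	C	C	0.45	3.40	0.36	-0.10	1.70	0
APO	O	O	-0.45	2.96	0.88	-0.40	1.52	0
APO	CB	C	0.10	3.50	0.49	0.60	1.75	0
POL	N	N	-0.30	3.25	0.71	-0.50	1.55	0
POL	CA	C	0.45	3.40	0.36	0.05	1.70	0
POL	C	C	0.45	3.40	0.36	-0.10	1.70	0
POL	O	O	-0.45	2.96	0.88	-0.40	1.52	0
POL	OG	O	-0.15	3.00	0.59	-0.60	1.52	0
SUG	OL	O	0.00	3.00	0.59	-0.40	1.52	0
SUG	C4	C	0.35	3.40	0.36	0.20	1.70	0
SUG	C5	C	0.20	3.40	0.36	0.20	1.70	0
SUG	O5	O	-0.60	3.00	0.59	-0.40	1.52	0
SUG	C1	C	0.45	3.40	0.36	0.20	1.70	0
SUG	C2	C	0.30	3.40	0.36	0.20	1.70	0
SUG	C3	C	0.30	3.40	0.36	0.20	1.70	0
SUG	C6	C	0.00	3.50	0.49	0.50	1.75	0
SUG	O2	O	-0.50	3.00	0.59	-0.55	1.52	0
SUG	O3	O	-0.50	3.00	0.59	-0.55	1.52	0
HOH	O	O	-0.834	3.15	0.64	-0.50	1.52	0
HOH	H1	H	0.417	0.40	0.19	-0.10	1.20	0
HOH	H2	H	0.417	0.40	0.19	-0.10	1.20	0
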