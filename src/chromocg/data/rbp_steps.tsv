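# chromocg rigid-base-pair step parameter table, version 1.0
# Equilibrium helical parameters and diagonal stiffness per unique dinucleotide
# step (sequence-dependent entries are approximate literature-consistent B-DNA
# values; AVG is the sequence-averaged fallback used when no sequence is given).
# Units: distances A, angles degrees; stiffness kcal/mol/A^2 and kcal/mol/deg^2.
# The 6-vector ordering everywhere in this package is
#   (shift, slide, rise, tilt, roll, twist)
step	shift0	slide0	rise0	tilt0	roll0	twist0	k_shift	k_slide	k_rise	k_tilt	k_roll	k_twist
AA	0.00	-0.20	3.32	-1.40	0.70	35.30	4.20	3.00	8.00	0.045	0.024	0.036
AC	0.10	-0.60	3.36	-0.50	0.70	31.50	4.00	2.80	7.50	0.042	0.022	0.034
AG	0.10	-0.30	3.36	-1.70	4.50	31.90	4.00	2.60	7.50	0.040	0.020	0.032
AT	0.00	-0.70	3.31	0.00	-0.80	29.30	4.40	3.20	8.20	0.046	0.026	0.038
CA	0.00	0.40	3.45	0.50	4.70	37.30	3.40	2.00	6.50	0.034	0.016	0.026
CC	0.10	-0.10	3.42	-0.10	3.60	32.90	3.80	2.40	7.00	0.038	0.019	0.030
CG	0.00	0.60	3.44	0.00	5.40	36.10	3.40	1.90	6.50	0.033	0.015	0.026
GA	-0.10	-0.10	3.40	-1.50	1.90	36.30	3.90	2.50	7.20	0.039	0.020	0.031
GC	0.00	-0.40	3.43	0.00	0.30	33.60	3.90	2.50	7.20	0.040	0.021	0.032
TA	0.00	0.10	3.42	0.00	3.30	37.80	3.20	1.80	6.20	0.031	0.014	0.024
AVG	0.00	-0.20	3.40	0.00	2.00	34.30	3.80	2.40	7.20	0.039	0.020	0.031
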