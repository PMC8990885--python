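# Fragment production probabilities per single cumulative-table draw, by
# elemental target, for 95 MeV/u carbon projectiles (percent, renormalized
# at load time). source = measured (thin-target experiment) or fluka-filled
# (cells the experiment could not access, filled from a full-MC simulation).
# target	species	probability_percent	source
H	n	14.0	fluka-filled
H	1H	38.0	measured
H	2H	5.0	measured
H	3H	1.3	measured
H	3He	3.0	measured
H	4He	26.0	measured
H	6He	3.6e-2	measured
H	6Li	2.3	measured
H	7Li	9.3e-1	measured
H	7Be	1.6	measured
H	9Be	2.5e-1	fluka-filled
H	10Be	1.0e-4	fluka-filled
H	8B	1.5e-1	fluka-filled
H	10B	1.3	fluka-filled
H	11B	2.1	fluka-filled
H	10C	1.9e-1	fluka-filled
H	11C	3.9	fluka-filled
H	12C	5.9e-1	fluka-filled
C	n	65.0	fluka-filled
C	1H	10.0	measured
C	2H	7.5	measured
C	3H	6.1	measured
C	3He	1.2	measured
C	4He	6.4	measured
C	6He	1.7	measured
C	6Li	2.5e-1	measured
C	7Li	4.1e-1	measured
C	7Be	8.3e-2	measured
C	9Be	1.1e-1	measured
C	10Be	2.4e-1	measured
C	8B	1.3e-2	measured
C	10B	8.9e-2	measured
C	11B	2.0e-1	measured
C	10C	1.7e-2	measured
C	11C	5.5e-2	measured
C	12C	4.3e-2	measured
O	n	60.0	fluka-filled
O	1H	16.0	measured
O	2H	8.8	measured
O	3H	5.1	measured
O	3He	1.7	measured
O	4He	6.3	measured
O	6He	1.0	measured
O	6Li	2.8e-1	measured
O	7Li	3.9e-1	measured
O	7Be	1.2e-1	measured
O	9Be	7.9e-2	measured
O	10Be	1.0e-1	measured
O	8B	1.4e-2	measured
O	10B	8.6e-2	measured
O	11B	1.8e-1	measured
O	10C	1.6e-2	measured
O	11C	7.1e-2	measured
O	12C	7.9e-2	measured
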