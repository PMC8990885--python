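# Two-component energy-angle emission parameters at the 95 MeV/u calibration
# energy, per (target element, fragment species):
#   f(E, theta) = A1 exp(-(alpha_E E + alpha_th theta))
#              + A2 exp(-(E-E_mean)^2/(2 sigma_E^2) - (theta-th_mean)^2/(2 sigma_th^2))
# Exponential term: target fragments. Gaussian term: projectile fragments.
# Units: E_mean, sigma_E in MeV/u; th_mean, sigma_th in degrees;
# alpha_E in 1/(MeV/u); alpha_th in 1/degree.
# target	species	A1	A2	E_mean	sigma_E	th_mean	sigma_th	alpha_E	alpha_th
H	n	5.4e-1	4.9e1	93	33	0.0	9.7	1.0e-2	2.5e-2
H	1H	5.4e-1	4.9e1	93	33	0.0	9.7	1.2e-2	2.5e-2
H	2H	2.0e-1	7.5	81	23	0.0	8.2	2.2e-2	6.5e-2
H	3H	7.8e-2	2.7	76	22	0.0	6.8	1.9e-2	1.8e-1
H	3He	2.2e-2	7.6	96	27	0.0	6.2	1.8e-2	1.0e-1
H	4He	9.8e-3	5.6e1	84	12	0.0	4.3	1.5e-2	1.8e-1
H	6He	3.0e-2	3.1	78	14	0.0	4.0	2.6e-2	2.7e-1
H	6Li	8.0e-3	4.5	84	11	0.0	3.4	1.9e-2	2.0e-1
H	7Li	1.9e-2	3.3	79	8.6	0.0	3.2	2.0e-2	2.7e-1
H	7Be	3.6e-3	6.6	85	11	0.0	3.1	1.7e-2	2.1e-1
H	9Be	2.0e-2	1.3	82	7.3	0.0	3.0	2.3e-2	2.7e-1
H	10Be	7.1e-2	3.8e-1	79	5.3	0.0	3.1	2.4e-2	3.2e-1
H	8B	6.3e-1	8.3e-3	89	13	0.0	3.2	2.2e-2	1.6e-1
H	10B	3.5e-3	1.3e1	83	6.5	0.0	2.5	1.9e-2	3.7e-1
H	11B	1.1e-2	1.4	83	4.6	0.0	2.2	1.8e-2	5.8e-1
H	10C	1.2e-3	3.7	88	7.2	0.0	2.3	1.8e-2	2.1e-1
H	11C	5.0e-4	3.9e1	84	4.8	0.0	2.1	1.7e-2	3.0e-1
H	12C	5.0e-4	9.3e1	83	3.6	0.0	9.2e-1	1.0e-2	2.0e-1
C	n	2.8e-1	1.0e2	93	37	0.0	1.0e1	1.2e-2	2.5e-2
C	1H	2.8e-1	1.0e2	93	37	0.0	1.0e1	1.3e-3	2.6e-2
C	2H	2.7e-1	5.4e1	81	26	0.0	8.9	2.6e-2	3.1e-2
C	3H	2.6e-1	2.5e1	73	18	0.0	7.6	3.2e-2	5.7e-2
C	3He	1.5e-1	3.6e1	92	29	0.0	7.0	3.1e-2	4.7e-2
C	4He	7.4e-2	1.9e2	83	15	0.0	5.2	2.9e-2	8.0e-2
C	6He	8.1e-2	1.0e1	78	17	0.0	5.4	3.0e-2	1.5e-1
C	6Li	7.0e-2	1.3e1	84	14	0.0	4.4	2.7e-2	1.1e-1
C	7Li	6.1e-2	1.3e1	79	13	0.0	4.2	3.1e-2	1.2e-1
C	7Be	3.7e-2	1.2e1	83	16	0.0	4.2	2.6e-2	1.2e-1
C	9Be	3.6e-2	5.7	83	11	0.0	3.7	2.5e-2	2.2e-1
C	10Be	4.8e-2	3.0	82	9.3	0.0	3.6	2.4e-2	2.7e-1
C	8B	1.8e-2	1.9	88	17	0.0	4.0	2.8e-2	1.5e-1
C	10B	7.7e-3	1.9e1	86	9.3	0.0	3.2	2.3e-2	2.1e-1
C	11B	8.4e-3	3.9e1	84	7.3	0.0	2.9	2.0e-1	3.0e-1
C	10C	5.9e-3	3.5	88	9.5	0.0	3.1	1.9e-2	2.1e-1
C	11C	3.4e-3	3.0	86	7.2	0.0	2.7	1.9e-2	2.6e-1
C	12C	3.5e-3	6.5e1	88	4.9	0.0	2.3	1.6e-2	2.8e-1
O	n	3.0e-1	1.3e2	93	37	0.0	1.0e1	1.3e-2	2.4e-2
O	1H	3.0e-1	1.3e2	93	37	0.0	1.0e1	1.3e-2	2.4e-2
O	2H	3.0e-1	6.3e1	82	26	0.0	9.2	2.6e-2	3.0e-2
O	3H	2.6e-1	2.8e1	73	18	0.0	7.9	3.2e-2	5.6e-2
O	3He	1.5e-1	4.2e1	91	29	0.0	7.3	2.9e-2	4.3e-2
O	4He	8.3e-2	2.1e2	83	15	0.0	5.3	2.9e-2	7.8e-2
O	6He	8.1e-2	1.1e1	79	17	0.0	5.5	2.9e-2	1.4e-1
O	6Li	7.9e-2	1.5e1	84	14	0.0	4.5	2.8e-2	1.0e-1
O	7Li	6.3e-2	1.4e1	79	13	0.0	4.4	3.1e-2	1.1e-1
O	7Be	3.9e-2	1.3e1	83	16	0.0	4.3	2.7e-2	1.1e-1
O	9Be	3.1e-2	6.0	83	12	0.0	3.9	2.7e-2	1.8e-1
O	10Be	5.5e-2	3.2	82	8.8	0.0	3.7	2.4e-2	2.4e-1
O	8B	2.2e-2	2.1	89	17	0.0	4.1	2.9e-2	1.4e-1
O	10B	7.7e-3	1.9e1	84	9.3	0.0	3.3	2.6e-2	1.7e-1
O	11B	8.0e-3	3.1e1	85	7.1	0.0	2.9	2.1e-2	2.5e-1
O	10C	8.8e-3	3.5	88	9.2	0.0	3.2	2.3e-2	2.0e-1
O	11C	3.4e-3	3.0e1	86	7.1	0.0	2.8	2.0e-2	2.3e-1
O	12C	3.4e-3	6.2e1	87	4.7	0.0	2.4	1.7e-2	3.0e-1
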