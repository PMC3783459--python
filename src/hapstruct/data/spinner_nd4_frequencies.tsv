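haplotype	NSW	QLD	NT	South Africa	accession
SP1	0.625	0.492	0.505	0.468	KF612545
SP2	0.082	0.111	0.124	0.065	KF612546
SP3	0.005	0.032	0.010	0	KF612547
SP4	0.010	0.063	0.041	0.016	KF612548
SP5	0	0	0.010	0	KF612549
SP6	0.019	0	0.010	0	KF612550
SP7	0	0	0	0.065	KF612551
SP8	0.005	0.016	0.031	0	KF612552
SP9	0	0	0	0.032	KF612553
SP10	0	0.016	0	0.145	KF612554
SP11	0	0	0.010	0.016	KF612555
SP12	0	0	0.021	0.048	KF612556
SP13	0	0	0.010	0.016	KF612557
SP14	0	0	0.010	0	KF612558
SP15	0	0	0.010	0	KF612559
SP16	0	0	0.010	0	KF612560
SP17	0.019	0.016	0.021	0.032	KF612561
SP18	0.053	0.048	0.021	0	KF612562
SP19	0	0	0.010	0	KF612563
SP20	0	0.016	0.010	0	KF612564
SP21	0.038	0	0.041	0	KF612565
SP22	0.024	0.063	0.021	0	KF612566
SP23	0.005	0	0.010	0	KF612567
SP24	0.005	0	0.010	0	KF612568
SP25	0	0.016	0	0	KF612569
SP26	0	0.016	0	0	KF612570
SP27	0.005	0.016	0	0	KF612571
SP28	0.005	0.016	0	0	KF612572
SP29	0.019	0.016	0.010	0	KF612573
SP30	0.010	0.016	0	0	KF612574
SP31	0.010	0	0	0	KF612575
SP32	0.010	0	0	0	KF612576
SP33	0.014	0	0	0	KF612577
SP34	0.005	0	0	0	KF612578
SP35	0.005	0	0	0	KF612579
SP36	0.019	0.032	0.041	0.097	KF612580
SP37	0.010	0	0	0	KF612581
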