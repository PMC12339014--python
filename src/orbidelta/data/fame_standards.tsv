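# Methyl stearate (C19H38O2) standards validation set.
# expected_vpdb: GC-C-IRMS reference value of each standard (delta 13C vs VPDB, permil).
# delta_vpdb / sd: ESI-Orbitrap measurement per introduction method and adduct.
# residue_printed: measured - expected residue as published alongside the measurements.
# The working reference standard is -27.8 +- 0.4 permil vs VPDB.
std	method	adduct	delta_vpdb	sd	expected_vpdb	residue_printed
1	dual_inlet	MH	-30.6	0.1	-29.5	-1.1
2	dual_inlet	MH	-30.5	0.3	-29.8	-0.7
3	dual_inlet	MH	-30.1	0.3	-29.2	-0.9
4	dual_inlet	MH	-29.8	0.5	-29.0	-0.8
5	dual_inlet	MH	-27.9	0.3	-27.4	-0.5
6	dual_inlet	MH	-30.2	0.3	-29.6	-0.6
7	dual_inlet	MH	-30.2	0.2	-29.6	-0.6
8	dual_inlet	MH	-29.9	0.4	-28.9	-1.0
9	dual_inlet	MH	-29.7	0.3	-28.5	-1.7
1	dual_inlet	MNa	-29.6	0.1	-29.5	-0.1
2	dual_inlet	MNa	-29.8	0.2	-29.8	0.0
3	dual_inlet	MNa	-29.3	0.5	-29.2	-0.1
4	dual_inlet	MNa	-28.3	0.3	-29.0	0.7
5	dual_inlet	MNa	-26.5	0.6	-27.4	0.9
6	dual_inlet	MNa	-28.7	0.2	-29.6	0.9
7	dual_inlet	MNa	-28.4	0.1	-29.6	1.2
8	dual_inlet	MNa	-27.0	0.3	-28.9	1.9
9	dual_inlet	MNa	-27.3	0.6	-28.5	0.7
1	hplc	MH	-28.8	0.4	-29.5	0.7
2	hplc	MH	-29.8	1.0	-29.8	0.0
3	hplc	MH	-28.1	0.4	-29.2	1.1
4	hplc	MH	-28.4	0.4	-29.0	0.6
5	hplc	MH	-27.2	0.9	-27.4	0.2
6	hplc	MH	-29.2	0.2	-29.6	0.4
7	hplc	MH	-28.6	0.5	-29.6	1.0
8	hplc	MH	-28.9	1.0	-28.9	0.0
9	hplc	MH	-27.5	0.5	-28.5	0.5
1	hplc	MNa	-29.1	0.2	-29.5	0.4
2	hplc	MNa	-29.7	0.4	-29.8	0.1
3	hplc	MNa	-28.9	0.9	-29.2	0.3
4	hplc	MNa	-27.4	0.8	-29.0	1.6
5	hplc	MNa	-26.7	0.7	-27.4	0.7
6	hplc	MNa	-28.7	0.2	-29.6	0.9
7	hplc	MNa	-28.5	0.6	-29.6	1.1
8	hplc	MNa	-28.4	0.4	-28.9	0.5
9	hplc	MNa	-27.1	0.3	-28.5	0.9
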