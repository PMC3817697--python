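name	mass_kda	n	approach
Apc1	216.5	1	docking
Apc2	93.8	1	docking
Apc3	91.9	2	subunit_deletion
Apc4	92.1	1	fab_em
Apc5	85.1	1	elimination
Apc6	71.7	2	subunit_deletion
Apc7	66.9	2	subunit_deletion
Apc8	68.8	2	subunit_deletion
Apc10	21.2	1	subunit_deletion
Apc11	9.8	1	nd
Apc13	8.5	1	nd
Apc15	14.3	1	nd
Apc16	11.7	1	nd
Cdc26	9.8	2	subunit_deletion
Cdc20	54.7	1	subunit_deletion
Cdh1	55.2	1	subunit_deletion
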