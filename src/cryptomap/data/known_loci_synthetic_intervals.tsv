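gp	backcross	tclass	chrom	start	end	allele	peak_score	gene
GPb	BY	21	chr02	100000	130000	BY	10.0	SRB6
GPc	BY	21	chr02	200000	230000	3S	10.0	IRA1
GPa	BY	21	chr04	100000	130000	3S	10.0	TRR1
GPc	BY	21	chr04	200000	230000	3S	10.0	GPI8
GPc	BY	21	chr05	100000	130000	3S	10.0	GCN4
GPa	BY	21	chr05	200000	230000	3S	10.0	FLO8
GPb	BY	21	chr05	208000	238000	3S	10.0	FLO8
GPc	BY	21	chr05	300000	330000	BY	10.0	PMD1
GPb	BY	21	chr07	100000	130000	3S	10.0	MDS3
GPa	BY	21	chr07	200000	230000	BY	10.0	MGA1
GPb	BY	21	chr07	208000	238000	BY	10.0	MGA1
GPc	BY	21	chr08	100000	130000	BY	10.0	GPA1
GPa	BY	21	chr09	100000	130000	3S	10.0	FLO11
GPb	BY	21	chr09	108000	138000	3S	10.0	FLO11
GPc	BY	21	chr09	116000	146000	3S	10.0	FLO11
GPb	BY	21	chr09	200000	230000	BY	10.0	prFLO11
GPc	BY	21	chr09	208000	238000	BY	10.0	prFLO11
GPb	BY	21	chr11	100000	130000	BY	10.0	TPK3
GPc	BY	21	chr12	100000	130000	BY	10.0	SDC25
GPa	BY	21	chr12	200000	230000	3S	10.0	YPT6
GPc	BY	21	chr12	208000	238000	3S	10.0	YPT6
GPa	BY	21	chr13	100000	130000	BY	10.0	MSS11
GPb	BY	21	chr13	108000	138000	3S	10.0	MSS11
GPb	BY	21	chr14	100000	130000	BY	10.0	SRV2
GPa	BY	21	chr14	200000	230000	BY	10.0	END3
GPc	BY	21	chr14	208000	238000	3S	10.0	END3
GPb	BY	21	chr15	100000	130000	BY	10.0	IRA2
GPc	BY	21	chr15	108000	138000	BY	10.0	IRA2
GPa	BY	21	chr15	200000	230000	BY	10.0	SFL1
GPb	BY	21	chr15	208000	238000	BY	10.0	SFL1
GPc	BY	21	chr16	100000	130000	3S	10.0	DIG1
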