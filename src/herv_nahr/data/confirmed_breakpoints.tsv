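# Molecularly confirmed HERV-HERV CNV breakpoint calls (GRCh37/hg19, 1-based).
# Bounds: start_max < start_min <= stop_min < stop_max; the crossover lies
# between the flanking informative cis-morphisms on each side.
#patient	locus	type	chrom	start_max	start_min	stop_min	stop_max
1	1q41	Del	chr1	222150405	222150567	223201703	223201865
2	1q41	Del	chr1	222150567	222150621	223201865	223201919
3	2p12	Dup	chr2	75444928	75444972	76804990	76805034
4	2p12	Del	chr2	77318677	77318740	78195410	78195473
5	2p12	Del	chr2	77318677	77318740	78195410	78195473
6	2p12	Del	chr2	77318421	77318561	78195154	78195294
7	2p12	Dup	chr2	77318269	77318318	78195002	78195051
8	11q24.3	Del	chr11	130434794	130434845	130623915	130623967
9	11q24.3	Del	chr11	130434721	130434729	130623842	130623850
10	11q24.3	Dup	chr11	130434903	130434960	130624026	130624082
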