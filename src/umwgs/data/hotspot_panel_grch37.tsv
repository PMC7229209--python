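gene	codon	chrom	pos	ref	alt
GNAQ	48	9	80537112	G	T
GNAQ	183	9	80412493	G	A
GNAQ	209	9	80409488	T	G
GNA11	183	19	3115819	C	T
GNA11	209	19	3118942	A	T
SF3B1	625	2	198267491	C	G
SF3B1	666	2	198266834	T	C
SF3B1	700	2	198266611	T	C
PLCB4	630	20	9389672	G	T
CYSLTR2	129	13	49281272	T	A
EIF1AX	1	X	20159898	C	T
EIF1AX	2	X	20159895	C	T
EIF1AX	3	X	20159892	C	T
EIF1AX	4	X	20159889	C	T
EIF1AX	5	X	20159886	C	T
EIF1AX	6	X	20159883	C	T
EIF1AX	7	X	20159880	C	T
EIF1AX	8	X	20159877	C	T
EIF1AX	9	X	20159874	C	T
EIF1AX	10	X	20159871	C	T
EIF1AX	11	X	20159868	C	T
EIF1AX	12	X	20159865	C	T
EIF1AX	13	X	20159862	C	T
EIF1AX	14	X	20159859	C	T
EIF1AX	15	X	20159856	C	T
EIF1AX	16	X	20159853	C	T
EIF1AX	17	X	20159850	C	T
EIF1AX	18	X	20159847	C	T
EIF1AX	19	X	20159844	C	T
EIF1AX	20	X	20159841	C	T
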