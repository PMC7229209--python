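gene	chrom	start	end
GNAQ	9	80331003	80646374
GNA11	19	3094408	3124002
PLCB4	20	9049052	9461531
CYSLTR2	13	49279178	49281951
BAP1	3	52435020	52444121
SF3B1	2	198254508	198299817
EIF1AX	X	20142636	20159962
TP53	17	7571720	7590868
RPL5	1	93297602	93307481
CENPE	4	104059593	104155164
MBD4	3	129149788	129159022
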