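arm	chrom	start	end
1p	1	1	125000000
1q	1	125000001	249250621
2p	2	1	93300000
2q	2	93300001	243199373
3p	3	1	91000000
3q	3	91000001	198022430
4p	4	1	50400000
4q	4	50400001	191154276
5p	5	1	48400000
5q	5	48400001	180915260
6p	6	1	61000000
6q	6	61000001	171115067
7p	7	1	59900000
7q	7	59900001	159138663
8p	8	1	45600000
8q	8	45600001	146364022
9p	9	1	49000000
9q	9	49000001	141213431
10p	10	1	40200000
10q	10	40200001	135534747
11p	11	1	53700000
11q	11	53700001	135006516
12p	12	1	35800000
12q	12	35800001	133851895
13p	13	1	17900000
13q	13	17900001	115169878
14p	14	1	17600000
14q	14	17600001	107349540
15p	15	1	19000000
15q	15	19000001	102531392
16p	16	1	36600000
16q	16	36600001	90354753
17p	17	1	24000000
17q	17	24000001	81195210
18p	18	1	17200000
18q	18	17200001	78077248
19p	19	1	26500000
19q	19	26500001	59128983
20p	20	1	27500000
20q	20	27500001	63025520
21p	21	1	13200000
21q	21	13200001	48129895
22p	22	1	14700000
22q	22	14700001	51304566
Xp	X	1	60600000
Xq	X	60600001	155270560
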