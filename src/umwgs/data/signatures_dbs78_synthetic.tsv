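Type	DBS1	DBSflat
AC>CA	0.00236764	0.01144452
AC>CG	0.00145759	0.01349695
AC>CT	0.00150521	0.00749411
AC>GA	0.00181168	0.01313045
AC>GG	0.00192960	0.01148285
AC>GT	0.00177781	0.01340186
AC>TA	0.00188320	0.01136173
AC>TG	0.00200270	0.01573679
AC>TT	0.00176621	0.01374705
AT>CA	0.00225784	0.01544728
AT>CC	0.00181945	0.01683777
AT>CG	0.00189898	0.00850131
AT>GA	0.00198997	0.01401479
AT>GC	0.00243428	0.01343731
AT>TA	0.00194615	0.01095334
CC>AA	0.00175929	0.01180492
CC>AG	0.00172837	0.01560842
CC>AT	0.00163454	0.01355924
CC>GA	0.00190109	0.01149018
CC>GG	0.00199807	0.01231695
CC>GT	0.00184394	0.01211378
CC>TA	0.00204486	0.01397216
CC>TG	0.00198152	0.01221413
CC>TT	0.85000000	0.01131334
CG>AA	0.00221023	0.01142018
CG>AC	0.00271895	0.01582905
CG>AT	0.00152910	0.01275495
CG>GA	0.00268969	0.01577436
CG>GC	0.00164897	0.01340926
CG>TA	0.00162948	0.01174232
CT>AA	0.00223856	0.01502451
CT>AC	0.00165158	0.01326720
CT>AG	0.00186932	0.01453737
CT>GA	0.00206365	0.01529909
CT>GC	0.00208370	0.01352019
CT>GG	0.00188930	0.01547956
CT>TA	0.00192452	0.01412813
CT>TC	0.00209340	0.01453841
CT>TG	0.00183178	0.01352246
GC>AA	0.00187472	0.01288575
GC>AG	0.00216127	0.01359608
GC>AT	0.00246429	0.01179306
GC>CA	0.00169884	0.01540969
GC>CG	0.00180390	0.00996277
GC>TA	0.00222095	0.01337024
TA>AC	0.00203518	0.01035570
TA>AG	0.00198951	0.01430801
TA>AT	0.00158939	0.01149810
TA>CC	0.00123623	0.01108895
TA>CG	0.00193174	0.01011553
TA>GC	0.00240785	0.01277496
TC>AA	0.00219402	0.01118155
TC>AG	0.00168024	0.01253641
TC>AT	0.00246784	0.00838795
TC>CA	0.00195862	0.01302858
TC>CG	0.00258364	0.01226082
TC>CT	0.00245176	0.01541198
TC>GA	0.00186121	0.01030488
TC>GG	0.00172246	0.01208919
TC>GT	0.00235946	0.01211641
TG>AA	0.00173702	0.01287107
TG>AC	0.00243146	0.01083542
TG>AT	0.00195878	0.01590069
TG>CA	0.00157865	0.01650648
TG>CC	0.00185201	0.01437325
TG>CT	0.00212122	0.01485669
TG>GA	0.00176171	0.01130852
TG>GC	0.00247942	0.00995592
TG>GT	0.00185008	0.01225805
TT>AA	0.00195789	0.01138174
TT>AC	0.00124238	0.01230215
TT>AG	0.00148303	0.01487136
TT>CA	0.00189487	0.01187922
TT>CC	0.00156844	0.01406617
TT>CG	0.00169827	0.01264600
TT>GA	0.00224362	0.01036240
TT>GC	0.00171325	0.01137312
TT>GG	0.00192257	0.01264687
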