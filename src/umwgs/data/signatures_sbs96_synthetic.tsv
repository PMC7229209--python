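Type	SBS1	SBS5	SBS7a	SBS7b
A[C>A]A	0.00257290	0.00973172	0.00081187	0.00132203
A[C>A]C	0.00223630	0.00908781	0.00093844	0.00121913
A[C>A]G	0.00259638	0.00885677	0.00135688	0.00111887
A[C>A]T	0.00170354	0.01120961	0.00117527	0.00105114
C[C>A]A	0.00207532	0.00929470	0.00112837	0.00135973
C[C>A]C	0.00218554	0.01054420	0.00112404	0.00117301
C[C>A]G	0.00224534	0.01008197	0.00068861	0.00130716
C[C>A]T	0.00225237	0.01350576	0.00113295	0.00100434
G[C>A]A	0.00159244	0.01023479	0.00121006	0.00095278
G[C>A]C	0.00251700	0.01046939	0.00110050	0.00119481
G[C>A]G	0.00198128	0.01070228	0.00117843	0.00110733
G[C>A]T	0.00235346	0.01145005	0.00099214	0.00098352
T[C>A]A	0.00228876	0.00797134	0.00122708	0.00089610
T[C>A]C	0.00230961	0.01045314	0.00097115	0.00113500
T[C>A]G	0.00219159	0.00999964	0.00127116	0.00133910
T[C>A]T	0.00259642	0.00916194	0.00115254	0.00095818
A[C>G]A	0.00187250	0.00968367	0.00136698	0.00111042
A[C>G]C	0.00200786	0.00923870	0.00095620	0.00083496
A[C>G]G	0.00189868	0.00843950	0.00150866	0.00127407
A[C>G]T	0.00313080	0.01055389	0.00092633	0.00123153
C[C>G]A	0.00254923	0.01118805	0.00105937	0.00112483
C[C>G]C	0.00199721	0.01372551	0.00129480	0.00090878
C[C>G]G	0.00151203	0.00912732	0.00149712	0.00113957
C[C>G]T	0.00218448	0.01147112	0.00091136	0.00103143
G[C>G]A	0.00251874	0.01269492	0.00102415	0.00109210
G[C>G]C	0.00211978	0.01314074	0.00068088	0.00110531
G[C>G]G	0.00160799	0.01072295	0.00133059	0.00127550
G[C>G]T	0.00214358	0.01252333	0.00113821	0.00073104
T[C>G]A	0.00178026	0.01101911	0.00152424	0.00120784
T[C>G]C	0.00205684	0.01108487	0.00116048	0.00131955
T[C>G]G	0.00190336	0.00922115	0.00127928	0.00116818
T[C>G]T	0.00219497	0.01284659	0.00105460	0.00120525
A[C>T]A	0.00194058	0.01186977	0.00124754	0.00129710
A[C>T]C	0.00238536	0.01112578	0.00102683	0.00109127
A[C>T]G	0.20000000	0.01299740	0.00092631	0.00108697
A[C>T]T	0.00237499	0.01203656	0.00135408	0.00116395
C[C>T]A	0.00239489	0.01016051	0.07500000	0.15000000
C[C>T]C	0.00160144	0.00964131	0.07500000	0.15000000
C[C>T]G	0.20000000	0.01251119	0.07500000	0.15000000
C[C>T]T	0.00235733	0.00922247	0.07500000	0.15000000
G[C>T]A	0.00209944	0.00919084	0.00098180	0.00129093
G[C>T]C	0.00186518	0.00885368	0.00121897	0.00099474
G[C>T]G	0.20000000	0.01150354	0.00093651	0.00144473
G[C>T]T	0.00226430	0.00973268	0.00126527	0.00096061
T[C>T]A	0.00192896	0.00940984	0.15000000	0.07500000
T[C>T]C	0.00242005	0.00905283	0.15000000	0.07500000
T[C>T]G	0.20000000	0.00735860	0.15000000	0.07500000
T[C>T]T	0.00181896	0.01025519	0.15000000	0.07500000
A[T>A]A	0.00198326	0.01099951	0.00127457	0.00089016
A[T>A]C	0.00168999	0.01061978	0.00122259	0.00132271
A[T>A]G	0.00186536	0.01208709	0.00140146	0.00093328
A[T>A]T	0.00226169	0.01233934	0.00114702	0.00117288
C[T>A]A	0.00207979	0.01325495	0.00084216	0.00117975
C[T>A]C	0.00264170	0.01215994	0.00148619	0.00118366
C[T>A]G	0.00232742	0.01135678	0.00090617	0.00107566
C[T>A]T	0.00142662	0.01036272	0.00072288	0.00107586
G[T>A]A	0.00148693	0.01042124	0.00132078	0.00116988
G[T>A]C	0.00258349	0.00973366	0.00107639	0.00096688
G[T>A]G	0.00250783	0.01027423	0.00100607	0.00140669
G[T>A]T	0.00221459	0.00969200	0.00100998	0.00115029
T[T>A]A	0.00265272	0.00926350	0.00112124	0.00093724
T[T>A]C	0.00214374	0.00989116	0.00088284	0.00108778
T[T>A]G	0.00180479	0.00752146	0.00120437	0.00101592
T[T>A]T	0.00171622	0.00990677	0.00147709	0.00110605
A[T>C]A	0.00241800	0.00776188	0.00140105	0.00076169
A[T>C]C	0.00204642	0.01147112	0.00130079	0.00117276
A[T>C]G	0.00226720	0.01143538	0.00137156	0.00124382
A[T>C]T	0.00221981	0.00993323	0.00119994	0.00115100
C[T>C]A	0.00204187	0.01006416	0.00117076	0.00125313
C[T>C]C	0.00183744	0.00988600	0.00122821	0.00131656
C[T>C]G	0.00217108	0.01229730	0.00118170	0.00087079
C[T>C]T	0.00244016	0.01070334	0.00145295	0.00130498
G[T>C]A	0.00218215	0.01060730	0.00097811	0.00102299
G[T>C]C	0.00217957	0.01029554	0.00124706	0.00099650
G[T>C]G	0.00218348	0.01228521	0.00103666	0.00111565
G[T>C]T	0.00220539	0.00874866	0.00107771	0.00109926
T[T>C]A	0.00237317	0.01068704	0.00111172	0.00121812
T[T>C]C	0.00223123	0.00968975	0.00100668	0.00131157
T[T>C]G	0.00215375	0.01091797	0.00081326	0.00115071
T[T>C]T	0.00246781	0.00960691	0.00122217	0.00124025
A[T>G]A	0.00238678	0.00992346	0.00101682	0.00148391
A[T>G]C	0.00215734	0.01080535	0.00130102	0.00120230
A[T>G]G	0.00250438	0.00768809	0.00105026	0.00118225
A[T>G]T	0.00251222	0.01069769	0.00088943	0.00134140
C[T>G]A	0.00184569	0.01212776	0.00107594	0.00112932
C[T>G]C	0.00269661	0.00987222	0.00110966	0.00112557
C[T>G]G	0.00223613	0.00911635	0.00121255	0.00145261
C[T>G]T	0.00168365	0.01102742	0.00095908	0.00127241
G[T>G]A	0.00196934	0.00911661	0.00105057	0.00114062
G[T>G]C	0.00255456	0.01072547	0.00124998	0.00100634
G[T>G]G	0.00153550	0.00900868	0.00113358	0.00106458
G[T>G]T	0.00242464	0.01322843	0.00105280	0.00140042
T[T>G]A	0.00214202	0.01039805	0.00111991	0.00120688
T[T>G]C	0.00308138	0.00647224	0.00128549	0.00106671
T[T>G]G	0.00286217	0.00806481	0.00120618	0.00091601
T[T>G]T	0.00197482	0.01109380	0.00125455	0.00089131
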