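phenotype	locus	chrom	snp_printed	snp	a1	f_A_pct	f_U_pct	a2	chi2	p	or
IBD	U10	10	rs10761659	rs10761659	C	41.40	49.50	T	11.590	0.000662	0.7212
IBD	STX8	17	rs9895062	rs9895062	A	4.20	7.80	G	11.180	0.000827	0.5136
IBD	C6orf85	6	rs17309827	rs17309827	G	30.50	37.80	T	10.630	0.001115	0.7211
IBD	SLC22A4	5	rs1050152	rs1050152	C	42.00	34.50	T	10.530	0.001172	1.3780
IBD	5025133	5	rs2522057	rs2522057	C	40.50	33.80	G	8.415	0.003721	1.3360
IBD	5p13.1	5	rs17234657	rs17234657	C	9.90	6.40	T	7.038	0.007979	1.5920
IBD	RSHL1	19	rs8111071	rs8111071	A	14.30	10.10	G	7.017	0.008073	1.4880
IBD	TLR4	9	rs4986790	rs4986790	A	3.50	5.90	G	6.140	0.013210	0.5776
IBD	NFATC2	20	rs880324	rs880324	A	20.00	24.50	G	5.270	0.021700	0.7704
IBD	U1	1	rs17419032	rs17419032	A	19.40	23.80	T	4.760	0.029130	0.7745
IBD	STAT3	17	rs744166	rs744166	C	34.20	39.20	T	4.629	0.031430	0.8080
IBD	LYRM4	6	rs12529198	rs12529198	A	8.30	5.80	G	4.361	0.036760	1.4730
IBD	NKX2-3	10	rs10883365	rs10883365	A	44.40	49.20	G	3.902	0.048240	0.8248
CD	C6orf85	6	rs1730982	rs17309827	G	27.90	37.80	T	15.090	0.000102	0.6366
CD	U10	10	rs1076165	rs10761659	C	41.00	49.50	T	9.866	0.001684	0.7086
CD	RSHL1	19	rs8111071	rs8111071	A	15.30	10.10	G	8.528	0.003498	1.6200
CD	5p13.1	5	rs1723465	rs17234657	C	10.70	6.40	T	8.391	0.003771	1.7400
CD	SLC22A4	5	rs1050152	rs1050152	C	42.00	34.50	T	8.090	0.004450	1.3760
CD	5025133	5	rs2522057	rs2522057	C	41.20	33.80	G	7.692	0.005547	1.3710
CD	TLR4	9	rs4986790	rs4986790	A	2.90	5.90	G	7.427	0.006427	0.4780
CD	CARD15	16	rs2066847	rs2066847	-	3.20	1.20	C	7.023	0.008045	2.6890
CD	U17	17	rs4362447	rs4362447	C	42.20	35.30	T	6.819	0.009019	1.3420
CD	LYRM4	6	rs1252919	rs12529198	A	9.40	5.80	G	6.813	0.009050	1.6870
CD	STX8	17	rs9895062	rs9895062	A	4.40	7.80	G	6.786	0.009190	0.5499
CD	APG16L	2	rs2241880	rs2241880	C	36.10	42.80	T	5.956	0.014660	0.7575
CD	PPARG1	6	rs2960422	rs2960422	A	35.90	41.90	G	4.982	0.025610	0.7768
CD	STAT3	17	rs744166	rs744166	C	33.50	39.20	T	4.696	0.030240	0.7803
CD	PPARG	3	rs1801282	rs1801282	A	5.30	8.10	G	4.396	0.036020	0.6385
CD	POU2F1	1	rs2814036	rs2814036	A	2.70	1.20	G	4.299	0.038140	2.2540
CD	ATCL8	1	rs7547331	rs7547331	C	27.00	32.00	T	3.916	0.047840	0.7855
B1	C6orf85	6	rs17309827	rs17309827	G	27.80	37.80	T	11.860	0.000572	0.6342
B1	CARD15	16	rs2066847	rs2066847	-	4.00	1.20	C	10.980	0.000922	3.4740
B1	LYRM4	6	rs12529198	rs12529198	A	10.90	5.80	G	10.340	0.001305	1.9870
B1	POU2F1	1	rs2814036	rs2814036	A	3.90	1.20	G	9.246	0.002360	3.2400
B1	5025133	5	rs2522057	rs2522057	C	42.60	33.80	G	8.519	0.003515	1.4530
B1	U10	10	rs10761659	rs10761659	C	40.80	49.50	T	8.069	0.004502	0.7044
B1	SLC22A4	5	rs1050152	rs1050152	C	42.20	34.50	T	6.716	0.009557	1.3860
B1	TLR4	9	rs4986790	rs4986790	A	2.80	5.90	G	6.228	0.012570	0.4493
B1	5p13.1	5	rs17234657	rs17234657	C	10.40	6.40	T	5.912	0.015040	1.6860
B1	RSHL1	19	rs8111071	rs8111071	A	14.90	10.10	G	5.777	0.016240	1.5660
B1	ATCL8	1	rs7547331	rs7547331	C	25.50	32.00	T	5.005	0.025280	0.7286
B1	U7	7	rs1558043	rs1558043	C	12.80	17.90	G	4.948	0.026120	0.6744
B1	NKX2-3	10	rs7081330	rs7081330	A	40.10	33.60	G	4.944	0.026180	1.3220
B1	U13	13	rs11617463	rs11617463	A	8.90	5.80	C	4.202	0.040370	1.6040
B1	STX8	17	rs9895062	rs9895062	A	4.70	7.80	G	4.102	0.042830	0.5901
B2	APG16L	2	rs2241880	rs2241880	C	32.00	42.80	T	6.000	0.014310	0.6299
B2	PPARG	3	rs1801282	rs1801282	A	2.90	8.10	G	5.620	0.017760	0.3433
B2	C6orf85	6	rs17309827	rs17309827	G	28.30	37.80	T	5.008	0.025230	0.6488
B2	U17	17	rs4362447	rs4362447	C	44.70	35.30	T	4.893	0.026970	1.4860
B2	5p13.1	5	rs17234657	rs17234657	C	11.40	6.40	T	4.854	0.027580	1.8670
B2	FLJ44299	16	rs8050910	rs8050910	G	25.70	34.90	T	4.606	0.031860	0.6455
B2	NKX2-3	10	rs10883365	rs10883365	A	39.60	49.20	G	4.502	0.033860	0.6761
B2	U10	10	rs10761659	rs10761659	C	40.00	49.50	T	4.302	0.038060	0.6802
B2	PPARG1	6	rs2960422	rs2960422	A	32.90	41.90	G	4.277	0.038630	0.6796
B3	RSHL1	19	rs8111071	rs8111071	A	20.50	10.10	G	4.751	0.029270	2.3010
UC	STX8	17	rs9895062	rs9895062	A	3.70	7.80	G	7.447	0.006353	0.4574
UC	NFATC2	20	rs880324	rs880324	A	18.40	24.50	G	5.590	0.018060	0.6965
UC	U10	10	rs10761659	rs10761659	C	42.10	49.50	T	5.826	0.015790	0.7404
UC	U9	9	rs7869487	rs7869487	C	24.50	30.00	T	3.960	0.046600	0.7558
UC	NKX2-3	10	rs10883365	rs10883365	A	42.50	49.20	G	4.653	0.031000	0.7624
UC	5025133	5	rs2522057	rs2522057	C	39.70	33.80	G	3.929	0.047470	1.2870
UC	SLC22A4	5	rs1050152	rs1050152	C	42.10	34.50	T	6.536	0.010570	1.3820
UC	CDKAL1	6	rs6908425	rs6908425	C	23.10	17.00	T	6.567	0.010390	1.4720
E1	U3	3	rs1462651	rs1462651	C	19.40	9.00	T	8.134	0.004345	2.4400
E1	5p13.1	5	rs17234657	rs17234657	C	14.30	6.40	T	6.064	0.013800	2.4200
E1	NCF4	22	rs4821544	rs4821544	C	52.90	38.00	T	5.833	0.015730	1.8340
E1	DLG5	10	rs1248696	rs1248696	C	0.00	7.40	T	5.538	0.018610	0.0000
E1	CYLD	16	rs17223195	rs17223195	A	27.00	40.90	G	5.444	0.019640	0.5352
E1	U13	13	rs11617463	rs11617463	A	12.50	5.80	C	5.087	0.024100	2.3370
E1	U10	10	rs6601764	rs6601764	C	56.90	44.10	T	4.421	0.035510	1.6790
E2	STX8	17	rs9895062	rs9895062	A	2.80	7.80	G	4.551	0.032910	0.3438
E2	CDKAL1	6	rs6908425	rs6908425	C	23.90	17.00	T	3.894	0.048450	1.5400
E3	NKX2-3	10	rs10883365	rs10883365	A	37.90	49.20	G	7.531	0.006065	0.6302
E3	5p13.1	5	rs1992660	rs1992660	C	28.80	38.30	T	5.832	0.015730	0.6513
E3	PGLYRP4	1	rs10888557	rs10888557	C	19.80	13.00	G	5.823	0.015820	1.6510
E3	5025133	5	rs2522057	rs2522057	C	43.10	33.80	G	5.715	0.016820	1.4830
E3	U10	10	rs10761659	rs10761659	C	40.00	49.50	T	5.546	0.018520	0.6802
E3	FLJ45139	21	rs2836753	rs2836753	C	47.80	38.40	T	5.448	0.019590	1.4690
E3	SLC22A4	5	rs1050152	rs1050152	C	43.50	34.50	T	5.249	0.021960	1.4620
E3	STX8	17	rs9895062	rs9895062	A	3.20	7.80	G	4.997	0.025390	0.3910
E3	C6orf85	6	rs17309827	rs17309827	G	29.20	37.80	T	4.657	0.030930	0.6787
E3	5p13.1	5	rs9292777	rs9292777	C	32.10	40.60	T	4.575	0.032440	0.6901
E3	FAF1	1	rs11205760	rs11205760	C	19.50	26.90	T	4.460	0.034700	0.6567
E3	FLJ45139	12	rs2836754	rs2836754	C	48.90	40.50	T	4.408	0.035770	1.4070
E3	NFATC2	20	rs880324	rs880324	A	17.60	24.50	G	4.126	0.042240	0.6561
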