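id	exo_1	exo_2	cell_1	cell_2
TX00000	651.9421	640.2501	503.4566	473.6759
TX00001	856.0925	789.8436	719.8399	666.8572
TX00002	1944.3152	2132.6141	2099.3707	2063.9220
TX00003	781.7854	765.5438	921.4028	967.2735
TX00004	275.0865	261.7517	308.3519	278.0621
TX00005	573.7629	625.6001	526.4424	542.4516
TX00006	250.3967	231.0867	221.9351	212.9276
TX00007	671.9594	729.1594	851.8981	844.0706
TX00008	516.9378	519.5804	398.6108	412.0008
TX00009	1359.8147	1388.3077	1260.6848	1350.9972
TX00010	655.4317	670.1978	572.4970	638.1250
TX00011	654.2373	664.9070	687.5207	662.5920
TX00012	1265.8878	1253.2656	753.2538	702.6262
TX00013	1482.3091	1476.5962	746.5239	764.7448
TX00014	1437.6481	1513.2440	768.4987	778.0791
TX00015	724.2963	720.4230	429.2068	361.2952
TX00016	2967.1929	2909.8084	1596.0494	1681.9896
TX00017	1620.4404	1630.3685	900.7962	969.0859
TX00018	1282.6288	1246.8636	716.4577	762.5030
TX00019	780.8193	753.9788	444.5364	461.5821
TX00020	1149.5576	1249.3228	768.8648	804.1793
TX00021	2028.6791	2070.0871	1093.3426	1061.0268
TX00022	583.1654	642.8390	306.0814	311.2429
TX00023	1191.5783	1282.1689	641.6344	658.7699
TX00024	1176.0125	1199.9963	501.4844	548.1332
TX00025	976.5799	979.5296	344.9749	315.8527
TX00026	4360.3979	4876.2781	1909.5738	1692.5784
TX00027	1314.4268	1281.9627	461.2496	470.8618
TX00028	1185.4759	1181.9997	530.0240	573.8899
TX00029	2735.0864	2650.5680	934.7162	874.1221
TX00030	575.1710	631.6870	269.8462	250.3788
TX00031	903.6401	1012.7814	407.8034	409.7899
TX00032	1613.9407	1661.2244	665.9375	672.3692
TX00033	1965.2802	1760.0101	834.5142	934.1368
TX00034	1188.9201	1102.9242	459.7107	466.3647
TX00035	1070.5677	1129.3697	591.3714	575.9323
TX00036	4455.5541	4348.9918	1288.9325	1234.3544
TX00037	566.4328	635.9415	182.6235	175.7612
TX00038	6599.0647	5739.0088	1685.5498	1843.7486
TX00039	528.9351	572.6738	133.9670	128.8675
TX00040	3778.8889	3811.5967	1144.5157	1231.3812
TX00041	1019.1509	929.7509	204.8618	213.3981
TX00042	1680.4946	1843.0437	456.2362	455.7457
TX00043	3032.9581	2944.8848	605.8430	575.9408
TX00044	1060.0210	1118.0912	240.2547	240.5207
TX00045	1254.9922	1293.0965	347.4015	322.6810
TX00046	654.0130	500.4660	155.9409	154.3135
TX00047	866.6117	964.0909	224.0124	237.7643
TX00048	2184.6056	2225.5074	402.3688	428.2419
TX00049	10604.3858	9655.5340	1149.1190	1138.2695
TX00050	2190.8684	2425.0440	313.8097	308.2098
TX00051	3060.4244	3356.6740	410.3395	427.7251
TX00052	3712.1719	3375.9204	508.2288	503.5852
TX00053	6228.1716	6484.8255	904.5444	821.7376
TX00054	1609.4108	1717.4586	194.4945	194.5123
TX00055	5021.0162	5127.3589	612.9460	596.5797
TX00056	2988.5100	3225.3320	407.6486	360.2771
TX00057	16828.4555	15592.6491	2316.1896	2322.4799
TX00058	16065.8841	15943.4421	1993.4565	2075.5339
TX00059	3602.7525	4033.1719	546.5784	529.6764
TX00060	15597.0936	16890.7747	957.6105	937.7020
TX00061	2835.9221	2748.1719	170.9020	185.7433
TX00062	5723.8197	6265.1709	477.0385	483.3479
TX00063	4517.2300	4310.4645	298.2815	284.7515
TX00064	8226.6606	8526.1239	701.5546	688.5219
TX00065	2830.7924	2738.9674	200.7603	180.4761
TX00066	6482.1881	6577.6178	649.2721	618.1153
TX00067	20902.7086	17175.7783	1195.7259	1173.1403
TX00068	16046.9290	14765.1343	1322.3087	1288.7989
TX00069	7805.4904	7463.5794	670.2908	618.9771
TX00070	13804.7969	13293.2550	973.6047	864.5867
TX00071	16417.0350	14359.5067	1117.6426	1118.8194
TX00072	11332.7870	11405.0288	415.3915	417.8814
TX00073	14470.4261	15134.8796	516.5398	519.2516
TX00074	49651.8114	49477.8355	1677.4884	1595.9917
TX00075	6823.5569	7155.5876	324.9452	306.8216
TX00076	6187.1159	5564.9477	193.7842	198.1730
TX00077	22109.9468	24275.7410	1177.1204	1184.2901
TX00078	6464.3198	6683.7053	318.0191	304.0541
TX00079	6695.4635	5932.3577	284.6121	278.4368
TX00080	8215.8461	8141.9168	298.7553	348.0201
TX00081	9017.9073	8530.8098	498.5280	537.2229
TX00082	8405.6949	8449.4478	319.2837	330.3644
TX00083	11678.8315	12433.1619	560.0163	579.9260
TX00084	48062.2454	50368.7151	513.3604	461.8870
TX00085	120860.3889	113668.1836	609.6287	604.3563
TX00086	28104.3720	28503.6690	394.9006	383.6393
TX00087	41719.8517	41002.7992	862.6380	793.5043
TX00088	42725.4866	47239.1713	1410.6476	1314.2424
TX00089	85755.4278	93475.5355	513.1007	504.5368
TX00090	7941.7386	7480.0088	126.7620	120.2625
TX00091	30268.3721	29300.9616	659.3814	770.5680
TX00092	69790.3893	69121.6162	532.1537	584.2784
TX00093	349915.2353	355038.7101	1155.4315	1154.3548
TX00094	38257.6433	36886.7494	782.0739	869.1547
TX00095	142701.8935	134986.8754	697.9150	718.2087
TX00096	890.2908	851.0933	0.0000	0.0000
TX00097	864.0373	827.0468	0.0000	0.0000
TX00098	454.6171	472.8159	0.0000	0.0000
TX00099	454.2045	468.4673	0.0000	0.0000
TX00100	1131.5420	1139.4106	0.0000	0.0000
TX00101	994.5605	925.1538	0.0000	0.0000
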