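id	half_life_h	cell_type
TX00000	2.1662	b_cell
TX00001	17.7513	b_cell
TX00002	17.0149	b_cell
TX00003	6.5883	b_cell
TX00004	5.3139	b_cell
TX00005	5.9119	b_cell
TX00006	20.6961	b_cell
TX00007	2.9267	b_cell
TX00008	68.3291	b_cell
TX00009	3.1520	b_cell
TX00010	9.1408	b_cell
TX00011	41.4411	b_cell
TX00012	4.2131	b_cell
TX00013	2.1854	b_cell
TX00014	3.4191	b_cell
TX00015	9.2328	b_cell
TX00016	3.3370	b_cell
TX00017	17.1425	b_cell
TX00018	26.0487	b_cell
TX00019	12.7992	b_cell
TX00020	11.2165	b_cell
TX00021	38.7902	b_cell
TX00022	5.6077	b_cell
TX00023	4.8813	b_cell
TX00024	37.3764	b_cell
TX00025	7.1658	b_cell
TX00026	6.0714	b_cell
TX00027	22.9611	b_cell
TX00028	20.8080	b_cell
TX00029	5.8227	b_cell
TX00030	45.3818	b_cell
TX00031	16.0144	b_cell
TX00032	7.9682	b_cell
TX00033	2.4447	b_cell
TX00034	2.1782	b_cell
TX00035	32.6036	b_cell
TX00036	3.4293	b_cell
TX00037	1.7579	b_cell
TX00038	3.5047	b_cell
TX00039	13.3347	b_cell
TX00040	9.0025	b_cell
TX00041	5.4753	b_cell
TX00042	2.8542	b_cell
TX00043	22.8446	b_cell
TX00044	7.9655	b_cell
TX00045	1.3392	b_cell
TX00046	3.2834	b_cell
TX00047	6.4296	b_cell
TX00048	3.5765	b_cell
TX00049	4.0760	b_cell
TX00050	5.2703	b_cell
TX00051	7.3729	b_cell
TX00052	11.0197	b_cell
TX00053	2.8305	b_cell
TX00054	5.5545	b_cell
TX00055	10.0773	b_cell
TX00056	8.9428	b_cell
TX00057	10.5515	b_cell
TX00058	9.2575	b_cell
TX00059	1.4981	b_cell
TX00060	8.2249	b_cell
TX00061	20.7348	b_cell
TX00062	4.5750	b_cell
TX00063	6.2984	b_cell
TX00064	3.7208	b_cell
TX00065	4.1568	b_cell
TX00066	1.8604	b_cell
TX00067	10.2759	b_cell
TX00068	7.4163	b_cell
TX00069	6.6825	b_cell
TX00070	2.9303	b_cell
TX00071	5.2690	b_cell
TX00072	0.3676	b_cell
TX00073	12.7347	b_cell
TX00074	2.3373	b_cell
TX00075	1.8187	b_cell
TX00076	4.0726	b_cell
TX00077	6.4024	b_cell
TX00078	8.7427	b_cell
TX00079	3.0559	b_cell
TX00080	4.5774	b_cell
TX00081	2.6509	b_cell
TX00082	2.0793	b_cell
TX00083	8.0158	b_cell
TX00084	2.8775	b_cell
TX00085	2.1467	b_cell
TX00086	4.8769	b_cell
TX00087	1.7869	b_cell
TX00088	17.1402	b_cell
TX00089	6.6764	b_cell
TX00090	3.2670	b_cell
TX00091	6.7626	b_cell
TX00092	2.9170	b_cell
TX00093	4.3735	b_cell
TX00094	20.0699	b_cell
TX00095	4.6606	b_cell
TX00096	5.1378	b_cell
TX00097	4.2953	b_cell
TX00098	4.0729	b_cell
TX00099	6.0231	b_cell
TX00100	1.3012	b_cell
TX00101	3.1804	b_cell
TX00000	2.5180	fibroblast
TX00001	4.1755	fibroblast
TX00002	10.9107	fibroblast
TX00003	11.8402	fibroblast
TX00004	12.8532	fibroblast
TX00005	7.9903	fibroblast
TX00006	5.3809	fibroblast
TX00007	11.3232	fibroblast
TX00008	6.9483	fibroblast
TX00009	2.7416	fibroblast
TX00010	7.4282	fibroblast
TX00011	28.6235	fibroblast
TX00012	9.2606	fibroblast
TX00013	4.4540	fibroblast
TX00014	5.3604	fibroblast
TX00015	9.3624	fibroblast
TX00016	8.4870	fibroblast
TX00017	8.9220	fibroblast
TX00018	5.4617	fibroblast
TX00019	17.9685	fibroblast
TX00020	2.7858	fibroblast
TX00021	2.2895	fibroblast
TX00022	2.8219	fibroblast
TX00023	10.8757	fibroblast
TX00024	14.6101	fibroblast
TX00025	36.9621	fibroblast
TX00026	44.0620	fibroblast
TX00027	17.2351	fibroblast
TX00028	9.7881	fibroblast
TX00029	17.5059	fibroblast
TX00030	2.9898	fibroblast
TX00031	5.1096	fibroblast
TX00032	15.2648	fibroblast
TX00033	4.9175	fibroblast
TX00034	12.0020	fibroblast
TX00035	4.0201	fibroblast
TX00036	12.5215	fibroblast
TX00037	13.2622	fibroblast
TX00038	8.8387	fibroblast
TX00039	2.6925	fibroblast
TX00040	1.9433	fibroblast
TX00041	3.3009	fibroblast
TX00042	2.3981	fibroblast
TX00043	6.8329	fibroblast
TX00044	8.2480	fibroblast
TX00045	4.1227	fibroblast
TX00046	2.8480	fibroblast
TX00047	1.2688	fibroblast
TX00048	20.6205	fibroblast
TX00049	9.7800	fibroblast
TX00050	8.6474	fibroblast
TX00051	21.2396	fibroblast
TX00052	52.7197	fibroblast
TX00053	15.2892	fibroblast
TX00054	4.5410	fibroblast
TX00055	6.3533	fibroblast
TX00056	2.3589	fibroblast
TX00057	4.6376	fibroblast
TX00058	10.2671	fibroblast
TX00059	25.9663	fibroblast
TX00060	7.5954	fibroblast
TX00061	7.2239	fibroblast
TX00062	12.3873	fibroblast
TX00063	9.8856	fibroblast
TX00064	5.1257	fibroblast
TX00065	7.6275	fibroblast
TX00066	2.7952	fibroblast
TX00067	12.6357	fibroblast
TX00068	5.8098	fibroblast
TX00069	7.7355	fibroblast
TX00070	7.9397	fibroblast
TX00071	10.2846	fibroblast
TX00072	5.3091	fibroblast
TX00073	1.9430	fibroblast
TX00074	13.9181	fibroblast
TX00075	7.3789	fibroblast
TX00076	3.6909	fibroblast
TX00077	2.8129	fibroblast
TX00078	8.6102	fibroblast
TX00079	7.0366	fibroblast
TX00080	5.5195	fibroblast
TX00081	17.6218	fibroblast
TX00082	12.0084	fibroblast
TX00083	5.1209	fibroblast
TX00084	4.0581	fibroblast
TX00085	4.2841	fibroblast
TX00086	7.4346	fibroblast
TX00087	6.3132	fibroblast
TX00088	11.7445	fibroblast
TX00089	1.0237	fibroblast
TX00090	2.6848	fibroblast
TX00091	22.9035	fibroblast
TX00092	6.1002	fibroblast
TX00093	8.7179	fibroblast
TX00094	4.4982	fibroblast
TX00095	10.2505	fibroblast
TX00096	15.0298	fibroblast
TX00097	3.9484	fibroblast
TX00098	11.7183	fibroblast
TX00099	3.9402	fibroblast
TX00100	24.2804	fibroblast
TX00101	14.0486	fibroblast
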