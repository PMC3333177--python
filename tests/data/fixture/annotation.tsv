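id	class
TX00000	mRNA
TX00001	mRNA
TX00002	mRNA
TX00003	mRNA
TX00004	mRNA
TX00005	mRNA
TX00006	mRNA
TX00007	mRNA
TX00008	mRNA
TX00009	mRNA
TX00010	mRNA
TX00011	mRNA
TX00012	mRNA
TX00013	mRNA
TX00014	mRNA
TX00015	mRNA
TX00016	mRNA
TX00017	mRNA
TX00018	mRNA
TX00019	mRNA
TX00020	mRNA
TX00021	mRNA
TX00022	mRNA
TX00023	mRNA
TX00024	ncRNA
TX00025	mRNA
TX00026	mRNA
TX00027	mRNA
TX00028	mRNA
TX00029	mRNA
TX00030	mRNA
TX00031	mRNA
TX00032	mRNA
TX00033	mRNA
TX00034	mRNA
TX00035	mRNA
TX00036	mRNA
TX00037	mRNA
TX00038	mRNA
TX00039	ncRNA
TX00040	mRNA
TX00041	ncRNA
TX00042	mRNA
TX00043	mRNA
TX00044	mRNA
TX00045	mRNA
TX00046	mRNA
TX00047	mRNA
TX00048	mRNA
TX00049	mRNA
TX00050	ncRNA
TX00051	mRNA
TX00052	mRNA
TX00053	mRNA
TX00054	mRNA
TX00055	ncRNA
TX00056	ncRNA
TX00057	mRNA
TX00058	mRNA
TX00059	mRNA
TX00060	mRNA
TX00061	mRNA
TX00062	mRNA
TX00063	mRNA
TX00064	ncRNA
TX00065	mRNA
TX00066	ncRNA
TX00067	mRNA
TX00068	mRNA
TX00069	mRNA
TX00070	mRNA
TX00071	mRNA
TX00072	mRNA
TX00073	mRNA
TX00074	mRNA
TX00075	mRNA
TX00076	ncRNA
TX00077	mRNA
TX00078	mRNA
TX00079	mRNA
TX00080	mRNA
TX00081	mRNA
TX00082	mRNA
TX00083	mRNA
TX00084	mRNA
TX00085	mRNA
TX00086	ncRNA
TX00087	ncRNA
TX00088	mRNA
TX00089	ncRNA
TX00090	mRNA
TX00091	mRNA
TX00092	mRNA
TX00093	ncRNA
TX00094	mRNA
TX00095	mRNA
TX00096	mRNA
TX00097	mRNA
TX00098	mRNA
TX00099	mRNA
TX00100	mRNA
TX00101	mRNA
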