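hsa04261	Adrenergic signaling in cardiomyocytes (synthetic membership)	BPG013	BPG031	BPG041	BPG046	BPG060	BPG061	BPG062	BPG063	BPG064	BPG065	BPG066
hsa04925	Aldosterone synthesis and secretion (synthetic membership)	BPG003	BPG004	BPG013	BPG034	BPG046	BPG048	BPG057	BPG067	BPG068	BPG069	BPG070	BPG071	BPG072
hsa04020	Calcium signaling (synthetic membership)	BPG018	BPG027	BPG031	BPG034	BPG049	BPG073	BPG074	BPG075	BPG076	BPG077	BPG078
hsa04260	Cardiac muscle contraction (synthetic membership)	BPG020	BPG031	BPG035	BPG048	BPG059	BPG079	BPG080	BPG081	BPG082	BPG083	BPG084
hsa04010	MAPK signaling pathway (synthetic membership)	BPG017	BPG022	BPG041	BPG049	BPG050	BPG085	BPG086	BPG087	BPG088	BPG089	BPG090
hsa04080	Neuroactive ligand receptor interaction (synthetic membership)	BPG030	BPG043	BPG049	BPG053	BPG055	BPG091	BPG092	BPG093	BPG094	BPG095	BPG096
hsa04614	Renin-angiotensin system (synthetic membership)	BPG001	BPG002	BPG003	BPG004	BPG005	BPG006	BPG007	BPG008
hsa04924	Renin secretion (synthetic membership)	BPG001	BPG002	BPG011	BPG016	BPG032	BPG036	BPG047	BPG097	BPG098	BPG099	BPG100	BPG101	BPG102
hsa04022	cGMP-PKG signaling pathway (synthetic membership)	BPG025	BPG028	BPG029	BPG055	BPG059	BPG103	BPG104	BPG105	BPG106	BPG107	BPG108
hsa04024	cAMP signaling pathway (synthetic membership)	BPG015	BPG026	BPG031	BPG033	BPG043	BPG109	BPG110	BPG111	BPG112	BPG113	BPG114
hsa04270	Vascular smooth muscle contraction (synthetic membership)	BPG016	BPG029	BPG041	BPG045	BPG050	BPG115	BPG116	BPG117	BPG118	BPG119	BPG120
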