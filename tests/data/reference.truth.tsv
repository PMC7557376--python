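drug_id	block	property
D0001	1	property-1
D0002	1	property-1
D0003	1	property-1
D0004	1	property-1
D0005	1	property-1
D0006	1	property-1
D0007	1	property-1
D0008	1	property-1
D0009	1	property-1
D0010	1	property-1
D0011	1	property-1
D0012	1	property-1
D0013	1	property-1
D0014	1	property-1
D0015	1	property-1
D0016	1	property-1
D0017	1	property-1
D0018	1	property-1
D0019	1	property-1
D0020	1	property-1
D0021	2	property-2
D0022	2	property-2
D0023	2	property-2
D0024	2	property-2
D0025	2	property-2
D0026	2	property-2
D0027	2	property-2
D0028	2	property-2
D0029	2	property-2
D0030	2	property-2
D0031	2	property-2
D0032	2	property-2
D0033	2	property-2
D0034	2	property-2
D0035	2	property-2
D0036	2	property-2
D0037	2	property-2
D0038	2	property-2
D0039	2	property-2
D0040	2	property-2
D0041	3	property-3
D0042	3	property-3
D0043	3	property-3
D0044	3	property-3
D0045	3	property-3
D0046	3	property-3
D0047	3	property-3
D0048	3	property-3
D0049	3	property-3
D0050	3	property-3
D0051	3	property-3
D0052	3	property-3
D0053	3	property-3
D0054	3	property-3
D0055	3	property-3
D0056	3	property-3
D0057	3	property-3
D0058	3	property-3
D0059	3	property-3
D0060	3	property-3
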