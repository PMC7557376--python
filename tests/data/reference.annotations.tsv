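drug_id	properties	source
D0001	property-1	literature
D0002	property-1	literature
D0003	property-1	database
D0004	property-2	database
D0005	property-1	literature
D0006	property-1	database
D0007	property-1	database
D0008	property-1	database
D0009	property-1	database
D0010	property-1	literature
D0011	property-1	database
D0012	property-2	literature
D0013	property-1	database
D0014	property-1	database
D0015	property-2	database
D0016	property-1	literature
D0017	property-1	literature
D0018	property-1	database
D0019	property-1	database
D0020	property-1	literature
D0021	property-2	database
D0022	property-3	database
D0023	property-2	literature
D0024	property-2	literature
D0025	property-2	literature
D0026	property-2	literature
D0027	property-2	database
D0028	property-3	literature
D0029	property-2	database
D0030	property-2	database
D0031	property-2	literature
D0032	property-2	database
D0033	property-2	literature
D0034	property-3	database
D0035	property-2	literature
D0036	property-2	database
D0037	property-2	database
D0038	property-3	literature
D0039	property-2	database
D0040	property-2	database
D0041	property-2	database
D0042	property-1	database
D0043	property-3	database
D0044	property-3	database
D0045	property-3	database
D0046	property-3	database
D0047	property-3	database
D0048	property-3	database
D0049	property-3	literature
D0050	property-3	literature
D0051	property-3	database
D0052	property-3	literature
D0053	property-3	database
D0054	property-3	database
D0055	property-3	database
D0056	property-3	database
D0057	property-3	database
D0058	property-3	database
D0059	property-1	literature
D0060	property-3	database
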