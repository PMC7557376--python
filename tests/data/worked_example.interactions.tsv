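drug_id	drug_name	target_id	target_name	action
Drug1	Drug 1	T1	Target 1	antagonist
Drug1	Drug 1	T2	Target 2	agonist
Drug1	Drug 1	T3	Target 3	antagonist
Drug2	Drug 2	T1	Target 1	antagonist
Drug2	Drug 2	T2	Target 2	agonist
Drug2	Drug 2	T3	Target 3	antagonist
Drug4	Drug 4	T1	Target 1	antagonist
Drug4	Drug 4	T2	Target 2	agonist
Drug4	Drug 4	T3	Target 3	agonist
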