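# synthetic stand-in table: region -> subnetwork
region_000	DMN
region_001	DMN
region_002	DMN
region_003	DMN
region_004	DMN
region_005	DMN
region_006	DMN
region_007	DMN
region_008	Visual
region_009	Visual
region_010	Visual
region_011	Visual
region_012	Visual
region_013	Visual
region_014	SensMot
region_015	SensMot
region_016	SensMot
region_017	SensMot
region_018	SensMot
region_019	SensMot
region_020	Auditory
region_021	Auditory
region_022	Auditory
region_023	Auditory
region_024	ExecCont
region_025	ExecCont
region_026	ExecCont
region_027	ExecCont
region_028	ExecCont
region_029	FronPar
region_030	FronPar
region_031	FronPar
region_032	FronPar
region_033	FronPar
region_034	DMN
region_035	DMN
region_036	DMN
region_037	DMN
region_038	DMN
region_039	DMN
region_040	DMN
region_041	DMN
region_042	Visual
region_043	Visual
region_044	Visual
region_045	Visual
region_046	Visual
region_047	Visual
region_048	SensMot
region_049	SensMot
region_050	SensMot
region_051	SensMot
region_052	SensMot
region_053	SensMot
region_054	Auditory
region_055	Auditory
region_056	Auditory
region_057	Auditory
region_058	ExecCont
region_059	ExecCont
region_060	ExecCont
region_061	ExecCont
region_062	ExecCont
region_063	FronPar
region_064	FronPar
region_065	FronPar
region_066	FronPar
region_067	FronPar
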