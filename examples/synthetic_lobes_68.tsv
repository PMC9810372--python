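# synthetic stand-in table: region -> subnetwork
region_000	frontal
region_001	frontal
region_002	frontal
region_003	frontal
region_004	frontal
region_005	frontal
region_006	frontal
region_007	frontal
region_008	frontal
region_009	frontal
region_010	parietal
region_011	parietal
region_012	parietal
region_013	parietal
region_014	parietal
region_015	parietal
region_016	temporal
region_017	temporal
region_018	temporal
region_019	temporal
region_020	temporal
region_021	temporal
region_022	occipital
region_023	occipital
region_024	occipital
region_025	occipital
region_026	occipital
region_027	cingulate
region_028	cingulate
region_029	cingulate
region_030	cingulate
region_031	cingulate
region_032	insula
region_033	insula
region_034	frontal
region_035	frontal
region_036	frontal
region_037	frontal
region_038	frontal
region_039	frontal
region_040	frontal
region_041	frontal
region_042	frontal
region_043	frontal
region_044	parietal
region_045	parietal
region_046	parietal
region_047	parietal
region_048	parietal
region_049	parietal
region_050	temporal
region_051	temporal
region_052	temporal
region_053	temporal
region_054	temporal
region_055	temporal
region_056	occipital
region_057	occipital
region_058	occipital
region_059	occipital
region_060	occipital
region_061	cingulate
region_062	cingulate
region_063	cingulate
region_064	cingulate
region_065	cingulate
region_066	insula
region_067	insula
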