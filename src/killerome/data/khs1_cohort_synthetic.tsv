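strain_id	khs1_genotype	species_origin	kills_cglabrata	killed_by_reference
SYN001	opal	cerevisiae	0	1
SYN002	opal	cerevisiae	0	1
SYN003	opal	cerevisiae	0	1
SYN004	opal	cerevisiae	0	1
SYN005	opal	cerevisiae	0	1
SYN006	opal	cerevisiae	0	1
SYN007	opal	cerevisiae	0	1
SYN008	opal	cerevisiae	0	1
SYN009	opal	cerevisiae	0	1
SYN010	opal	cerevisiae	0	1
SYN011	opal	cerevisiae	0	1
SYN012	opal	cerevisiae	0	1
SYN013	opal	cerevisiae	0	1
SYN014	opal	cerevisiae	0	1
SYN015	opal	cerevisiae	0	1
SYN016	opal	cerevisiae	0	1
SYN017	opal	cerevisiae	0	1
SYN018	opal_ochre	cerevisiae	0	1
SYN019	opal_ochre	cerevisiae	0	1
YJM326	absent		0	1
SYN021	opal	cerevisiae	0	0
SYN022	opal	cerevisiae	0	0
SYN023	opal	cerevisiae	0	0
SYN024	opal	cerevisiae	0	0
SYN025	opal	cerevisiae	0	0
SYN026	opal	cerevisiae	0	0
SYN027	opal	cerevisiae	0	0
SYN028	opal	cerevisiae	0	0
SYN029	opal	cerevisiae	0	0
SYN030	opal	cerevisiae	0	0
SYN031	full_length	paradoxus	1	0
SYN032	full_length	paradoxus	1	0
SYN033	full_length	paradoxus	1	0
SYN034	full_length	paradoxus	1	0
SYN035	full_length	paradoxus	1	0
SYN036	full_length	paradoxus	1	0
SYN037	full_length	paradoxus	1	0
SYN038	full_length	paradoxus	1	0
SYN039	full_length	paradoxus	1	0
SYN040	full_length	paradoxus	1	0
SYN041	full_length	paradoxus	1	0
SYN042	full_length	paradoxus	1	0
SYN043	full_length	paradoxus	1	0
SYN044	full_length	paradoxus	1	0
SYN045	full_length	paradoxus	1	0
SYN046	full_length	paradoxus	1	0
SYN047	full_length	paradoxus	1	0
SYN048	full_length	paradoxus	1	0
SYN049	full_length	paradoxus	1	0
SYN050	full_length	paradoxus	1	0
SYN051	full_length	paradoxus	1	0
SYN052	full_length	paradoxus	1	0
SYN053	full_length	paradoxus	1	0
SYN054	full_length	paradoxus	1	0
SYN055	full_length	paradoxus	1	0
SYN056	full_length	paradoxus	1	0
SYN057	full_length	paradoxus	1	0
SYN058	full_length	paradoxus	1	0
SYN059	full_length	paradoxus	1	0
SYN060	full_length	paradoxus	1	0
SYN061	full_length	paradoxus	1	0
SYN062	full_length	paradoxus	1	0
SYN063	full_length	paradoxus	1	0
SYN064	full_length	paradoxus	1	0
SYN065	full_length	paradoxus	1	0
SYN066	full_length	paradoxus	1	0
SYN067	full_length	paradoxus	1	0
SYN068	full_length	paradoxus	1	0
SYN069	full_length	paradoxus	1	0
SYN070	full_length	paradoxus	1	0
SYN071	full_length	paradoxus	1	0
SYN072	full_length	paradoxus	1	0
SYN073	full_length	paradoxus	1	0
SYN074	full_length	paradoxus	1	0
SYN075	full_length	paradoxus	1	0
SYN076	full_length	paradoxus	1	0
SYN077	full_length	paradoxus	1	0
SYN078	full_length	paradoxus	1	0
SYN079	full_length	paradoxus	1	0
SYN080	full_length	paradoxus	1	0
SYN081	full_length	paradoxus	1	0
SYN082	full_length	paradoxus	1	0
SYN083	full_length	cerevisiae	1	0
SYN084	full_length	cerevisiae	1	0
SYN085	full_length	cerevisiae	1	0
SYN086	full_length	cerevisiae	1	0
SYN087	full_length	cerevisiae	1	0
SYN088	full_length	cerevisiae	1	0
YJM1383	opal	cerevisiae	1	0
YJM1450	opal	cerevisiae	1	0
SYN091	opal	cerevisiae	1	1
SYN092	opal	cerevisiae	1	1
SYN093	opal	cerevisiae	1	1
SYN094	opal	cerevisiae	1	1
SYN095	opal	cerevisiae	1	1
SYN096	full_length	paradoxus	1	1
SYN097	full_length	paradoxus	1	1
SYN098	full_length	cerevisiae	1	1
SYN099	full_length	cerevisiae	1	1
SYN100	full_length	cerevisiae	1	1
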