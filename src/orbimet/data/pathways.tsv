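pathway_id	pathway_name	compound_id	formula
PW_TRP	tryptophan metabolism	M0001	C11H12N2O2
PW_TRP	tryptophan metabolism	M0002	C11H12N2O4
PW_TRP	tryptophan metabolism	M0003	C10H12N2O3
PW_TRP	tryptophan metabolism	M0004	C10H7NO3
PW_TRP	tryptophan metabolism	M0005	C7H7NO2
PW_TRP	tryptophan metabolism	M0006	C10H12N2O4
PW_TRP	tryptophan metabolism	M0007	C7H7NO3
PW_TRP	tryptophan metabolism	M0008	C10H7NO4
PW_TRP	tryptophan metabolism	M0009	C7H5NO4
PW_TRP	tryptophan metabolism	M0010	C6H5NO2
PW_TRP	tryptophan metabolism	M0011	C6H7NO3
PW_TRP	tryptophan metabolism	M0012	C6H7NO4
PW_TRP	tryptophan metabolism	M0013	C9H12N2O
PW_TRP	tryptophan metabolism	M0014	C10H12N2O
PW_TRP	tryptophan metabolism	M0015	C11H12N2O3
PW_TRP	tryptophan metabolism	M0016	C10H9NO3
PW_TRP	tryptophan metabolism	M0017	C10H12N2
PW_TRP	tryptophan metabolism	M0018	C8H7N
PW_TRP	tryptophan metabolism	M0019	C10H9NO
PW_TRP	tryptophan metabolism	M0020	C10H9NO2
PW_TRP	tryptophan metabolism	M0021	C11H9NO3
PW_TRP	tryptophan metabolism	M0022	C11H11NO3
PW_TRP	tryptophan metabolism	M0023	C13H16N2O2
PW_TRP	tryptophan metabolism	M0024	C12H14N2O2
PW_TRP	tryptophan metabolism	M0025	C9H7NO2
PW_TRP	tryptophan metabolism	M0026	C8H7NO
PW_TRP	tryptophan metabolism	M0027	C8H7NO3
PW_TRP	tryptophan metabolism	M0028	C9H9N
PW_TRP	tryptophan metabolism	M0029	C10H12N2O2
PW_ARG_PRO	arginine and proline metabolism	M0030	C6H14N4O2
PW_ARG_PRO	arginine and proline metabolism	M0031	C5H12N2O2
PW_ARG_PRO	arginine and proline metabolism	M0032	C6H13N3O3
PW_ARG_PRO	arginine and proline metabolism	M0033	C5H9NO2
PW_ARG_PRO	arginine and proline metabolism	M0034	C5H9NO3
PW_ARG_PRO	arginine and proline metabolism	M0035	C5H9NO4
PW_ARG_PRO	arginine and proline metabolism	M0036	C5H10N2O3
PW_ARG_PRO	arginine and proline metabolism	M0037	C4H9N3O2
PW_ARG_PRO	arginine and proline metabolism	M0038	C4H7N3O
PW_ARG_PRO	arginine and proline metabolism	M0039	C4H12N2
PW_ARG_PRO	arginine and proline metabolism	M0040	C7H19N3
PW_ARG_PRO	arginine and proline metabolism	M0041	C10H26N4
PW_ARG_PRO	arginine and proline metabolism	M0042	C5H14N4
PW_ARG_PRO	arginine and proline metabolism	M0043	C4H9NO2
PW_ARG_PRO	arginine and proline metabolism	M0044	C5H7NO2
PW_ARG_PRO	arginine and proline metabolism	M0045	C7H14N2O3
PW_ARG_PRO	arginine and proline metabolism	M0046	C10H18N4O6
PW_ARG_PRO	arginine and proline metabolism	M0047	C3H7N3O2
PW_ARG_PRO	arginine and proline metabolism	M0048	CH4N2O
PW_ARG_PRO	arginine and proline metabolism	M0049	C6H14N2O
PW_TYR	tyrosine metabolism	M0050	C9H11NO3
PW_TYR	tyrosine metabolism	M0051	C9H11NO4
PW_TYR	tyrosine metabolism	M0052	C8H11NO2
PW_TYR	tyrosine metabolism	M0053	C8H11NO3
PW_TYR	tyrosine metabolism	M0054	C9H13NO3
PW_TYR	tyrosine metabolism	M0055	C9H13NO2
PW_TYR	tyrosine metabolism	M0056	C8H11NO
PW_TYR	tyrosine metabolism	M0057	C8H11NO
PW_TYR	tyrosine metabolism	M0058	C9H10O4
PW_TYR	tyrosine metabolism	M0059	C9H8O4
PW_TYR	tyrosine metabolism	M0060	C8H8O4
PW_TYR	tyrosine metabolism	M0061	C8H8O3
PW_TYR	tyrosine metabolism	M0062	C8H8O5
PW_TYR	tyrosine metabolism	M0063	C10H15NO3
PW_TYR	tyrosine metabolism	M0064	C9H10O5
PW_TYR	tyrosine metabolism	M0065	C8H8O4
PW_TYR	tyrosine metabolism	M0066	C9H11NO2
PW_TYR	tyrosine metabolism	M0067	C9H10O4
PW_TYR	tyrosine metabolism	M0068	C9H8O3
PW_TYR	tyrosine metabolism	M0069	C15H11I4NO4
PW_HIS	histidine metabolism	M0070	C6H9N3O2
PW_HIS	histidine metabolism	M0071	C5H9N3
PW_HIS	histidine metabolism	M0072	C6H6N2O2
PW_HIS	histidine metabolism	M0073	C5H6N2O2
PW_HIS	histidine metabolism	M0074	C9H14N4O3
PW_HIS	histidine metabolism	M0075	C10H16N4O3
PW_HIS	histidine metabolism	M0076	C7H11N3O2
PW_HIS	histidine metabolism	M0077	C7H11N3O2
PW_HIS	histidine metabolism	M0078	C6H10N2O5
PW_HIS	histidine metabolism	M0079	C6H8N2O2
PW_HIS	histidine metabolism	M0080	C6H8N2O3
PW_HIS	histidine metabolism	M0081	C6H8N2O4
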