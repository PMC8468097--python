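C00001	pathway_B
C00001	pathway_F
C00002	pathway_B
C00002	pathway_C
C00003	pathway_B
C00003	pathway_D
C00005	pathway_B
C00005	pathway_C
C00006	pathway_C
C00006	pathway_F
C00007	pathway_A
C00007	pathway_D
C00008	pathway_C
C00009	pathway_B
C00009	pathway_E
C00010	pathway_F
C00011	pathway_A
C00014	pathway_C
C00015	pathway_E
C00016	pathway_D
C00016	pathway_E
C00017	pathway_D
C00018	pathway_F
C00019	pathway_D
C00020	pathway_A
C00020	pathway_F
C00021	pathway_A
C00021	pathway_C
C00022	pathway_E
C00023	pathway_B
C00024	pathway_A
C00025	pathway_A
C00025	pathway_F
C00026	pathway_A
C00026	pathway_F
C00029	pathway_D
C00030	pathway_A
C00031	pathway_D
C00032	pathway_C
C00033	pathway_D
C00033	pathway_E
C00034	pathway_B
C00036	pathway_A
C00036	pathway_C
C00037	pathway_D
C00037	pathway_E
C00039	pathway_E
C00040	pathway_A
C00041	pathway_B
C00041	pathway_D
C00042	pathway_B
C00042	pathway_E
C00043	pathway_A
C00043	pathway_D
C00044	pathway_C
C00044	pathway_E
C00046	pathway_B
C00046	pathway_C
C00047	pathway_F
C00048	pathway_C
C00051	pathway_A
C00051	pathway_E
C00052	pathway_E
C00053	pathway_A
C00055	pathway_D
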