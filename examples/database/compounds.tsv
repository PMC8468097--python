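C00001	compound 1
C00002	compound 2
C00003	compound 3
C00004	compound 4
C00005	compound 5
C00006	compound 6
C00007	compound 7
C00008	compound 8
C00009	compound 9
C00010	compound 10
C00011	compound 11
C00012	compound 12
C00013	compound 13
C00014	compound 14
C00015	compound 15
C00016	compound 16
C00017	compound 17
C00018	compound 18
C00019	compound 19
C00020	compound 20
C00021	compound 21
C00022	compound 22
C00023	compound 23
C00024	compound 24
C00025	compound 25
C00026	compound 26
C00027	compound 27
C00028	compound 28
C00029	compound 29
C00030	compound 30
C00031	compound 31
C00032	compound 32
C00033	compound 33
C00034	compound 34
C00035	compound 35
C00036	compound 36
C00037	compound 37
C00038	compound 38
C00039	compound 39
C00040	compound 40
C00041	compound 41
C00042	compound 42
C00043	compound 43
C00044	compound 44
C00045	compound 45
C00046	compound 46
C00047	compound 47
C00048	compound 48
C00049	compound 49
C00050	compound 50
C00051	compound 51
C00052	compound 52
C00053	compound 53
C00054	compound 54
C00055	compound 55
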