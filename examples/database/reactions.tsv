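R00001	2.2.2.1	C00001	C00004	forward
R00002	3.3.3.2	C00002	C00005	forward
R00003	4.4.4.3	C00003	C00006	forward
R00004	5.5.5.4	C00001;C00006	C00007	forward
R00005	6.6.6.5	C00002;C00003	C00008	forward
R00006	1.7.7.6	C00003	C00009	forward
R00007	2.8.8.7	C00002;C00009	C00010	forward
R00008	3.9.9.8	C00001;C00007	C00011	forward
R00009	4.1.1.9	C00002	C00012	forward
R00010	5.2.2.10	C00004	C00013	forward
R00011	6.3.3.11	C00009	C00014	reversible
R00012	1.4.4.12	C00009;C00012	C00015	forward
R00013	2.5.5.13	C00010	C00016	forward
R00014	3.6.6.14	C00006	C00017	forward
R00015	4.7.7.15	C00009	C00018	reversible
R00016	5.8.8.16	C00004	C00019	reversible
R00017	6.9.9.17	C00012	C00020	forward
R00018	1.1.1.18	C00002;C00009	C00021	forward
R00019	2.2.2.19	C00015;C00018	C00022	reversible
R00020	3.3.3.20	C00003	C00023	forward
R00021	4.4.4.21	C00010;C00021	C00024	forward
R00022	5.5.5.22	C00019	C00025	reversible
R00023	6.6.6.23	C00002	C00026	forward
R00024	1.7.7.24	C00008;C00025	C00027	forward
R00025	2.8.8.25	C00008	C00028	forward
R00026	3.9.9.26	C00009	C00029	forward
R00027	4.1.1.27	C00006	C00030	forward
R00028	5.2.2.28	C00022	C00031	forward
R00029	6.3.3.29	C00003;C00021	C00032	forward
R00030	1.4.4.30	C00011;C00016	C00033	reversible
R00031	2.5.5.31	C00018	C00034	forward
R00032	3.6.6.32	C00015;C00021	C00035	forward
R00033	4.7.7.33	C00015	C00036	forward
R00034	5.8.8.34	C00026	C00037	forward
R00035	6.9.9.35	C00037	C00038	forward
R00036	1.1.1.36	C00014	C00039	forward
R00037	2.2.2.37	C00030	C00040	reversible
R00038	3.3.3.38	C00016	C00041	forward
R00039	4.4.4.39	C00017;C00038	C00042	forward
R00040	5.5.5.40	C00024;C00026	C00043	forward
R00041	6.6.6.41	C00033	C00044	forward
R00042	1.7.7.42	C00008	C00045	reversible
R00043	2.8.8.43	C00044	C00046	forward
R00044	3.9.9.44	C00025	C00047	forward
R00045	4.1.1.45	C00034	C00048	forward
R00046	5.2.2.46	C00001;C00044	C00049	forward
R00047	6.3.3.47	C00008;C00044	C00050	forward
R00048	1.4.4.48	C00050	C00051	forward
R00049	2.5.5.49	C00011	C00022	forward
R00050	3.6.6.50	C00033	C00004	forward
R00051	4.7.7.51	C00050	C00020	forward
R00052	5.8.8.52	C00015	C00036	forward
R00053	6.9.9.53	C00044	C00023	forward
R00054	1.1.1.54	C00036	C00042	reversible
R00055	2.2.2.55	C00027	C00014	forward
R00056	3.3.3.56	C00037	C00004	forward
R00057	4.4.4.57	C00035	C00005	reversible
R00058	5.5.5.58	C00027	C00023	forward
R00059	6.6.6.59	C00019	C00040	forward
R00060	1.7.7.60	C00009	C00050	forward
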