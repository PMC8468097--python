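1.1.1.36	pathway_E
1.1.1.36	pathway_F
1.1.1.54	pathway_A
1.1.1.54	pathway_C
1.4.4.30	pathway_A
1.4.4.48	pathway_C
1.7.7.24	pathway_F
1.7.7.42	pathway_C
1.7.7.42	pathway_F
1.7.7.6	pathway_A
1.7.7.60	pathway_C
2.2.2.1	pathway_B
2.2.2.19	pathway_B
2.2.2.37	pathway_D
2.2.2.37	pathway_F
2.2.2.55	pathway_A
2.5.5.31	pathway_E
2.5.5.49	pathway_E
2.8.8.25	pathway_B
2.8.8.43	pathway_A
3.3.3.2	pathway_F
3.3.3.20	pathway_D
3.3.3.20	pathway_E
3.3.3.38	pathway_B
3.6.6.50	pathway_C
3.6.6.50	pathway_D
4.1.1.27	pathway_A
4.1.1.27	pathway_D
4.4.4.21	pathway_C
4.4.4.3	pathway_B
4.4.4.39	pathway_D
4.4.4.57	pathway_C
4.7.7.15	pathway_D
4.7.7.15	pathway_E
4.7.7.33	pathway_A
5.2.2.10	pathway_A
5.2.2.10	pathway_C
5.2.2.28	pathway_C
5.2.2.46	pathway_D
5.5.5.22	pathway_A
5.5.5.22	pathway_D
5.5.5.40	pathway_F
5.5.5.58	pathway_B
5.5.5.58	pathway_E
5.8.8.16	pathway_F
5.8.8.52	pathway_A
5.8.8.52	pathway_C
6.3.3.11	pathway_C
6.3.3.11	pathway_D
6.3.3.29	pathway_E
6.3.3.47	pathway_F
6.6.6.41	pathway_E
6.6.6.5	pathway_E
6.9.9.17	pathway_D
6.9.9.35	pathway_C
6.9.9.35	pathway_F
6.9.9.53	pathway_F
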