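SNPID	CHR	POS	Non_Effect_Allele	Effect_Allele	N_Samples	AF	Beta_Marginal	SE_Beta_Marginal	Beta_G	SE_Beta_G	Beta_G-e1	SE_Beta_G-e1	robust_SE_Beta_Marginal	robust_SE_Beta_G	robust_SE_Beta_G-e1	P_Value_Marginal	P_Value_Interaction	P_Value_Joint	STATUS
rs1	1	1000	A	B	100	0.295	0.0298327	0.161543	0.0244368	0.164779	0.0306984	0.160325	0.152645	0.149349	0.157142	8.450502e-01	8.451153e-01	9.685823e-01	ok
rs2	1	2000	A	B	100	0.41	-0.0415025	0.139125	-0.0484253	0.139584	-0.120922	0.144405	0.136482	0.138412	0.165401	7.610621e-01	4.647305e-01	7.517848e-01	ok
rs3	1	3000	A	B	100	0.335	0.0739681	0.156635	0.0556552	0.159431	-0.116689	0.173809	0.143873	0.147685	0.161223	6.071669e-01	4.692053e-01	6.395841e-01	ok
rs4	1	4000	A	B	100	0.165	0.275988	0.185565	0.297928	0.192066	0.0948224	0.201636	0.182549	0.188587	0.243957	1.305692e-01	6.975094e-01	2.867128e-01	ok
rs5	1	5000	A	B	100	0.155	0.0617916	0.204952	0.111403	0.196027	0.720644	0.22057	0.20751	0.187111	0.224887	7.658734e-01	1.353142e-03	5.809652e-03	ok
rs6	1	6000	A	B	100	0.37	0.219974	0.143087	0.217287	0.143118	0.156044	0.156663	0.140472	0.137567	0.217412	1.173580e-01	4.729207e-01	2.822810e-01	ok
rs7	1	7000	A	B	100	0.025	0.35054	0.453602	0.364585	0.450591	0.829768	0.542255	0.495819	0.397812	0.42051	4.795722e-01	4.846805e-02	7.369243e-02	ok
rs8	1	8000	A	B	100	0.38	-0.17757	0.133435	-0.180594	0.134407	-0.0399406	0.127416	0.116464	0.118395	0.125535	1.273402e-01	7.503606e-01	3.124393e-01	ok
rs9	1	9000	A	B	100	0.3	-0.00701345	0.144953	-0.00252967	0.144679	0.17893	0.1495	0.122253	0.124029	0.159792	9.542518e-01	2.628143e-01	5.339313e-01	ok
rs10	1	10000	A	B	100	0.22	0.0778577	0.155373	0.0823662	0.154486	0.226522	0.154294	0.12785	0.129906	0.139527	5.425384e-01	1.044819e-01	2.648229e-01	ok
rs11	1	11000	A	B	100	0.175	0.0836029	0.179732	0.0836809	0.180609	-0.0433278	0.176666	0.163607	0.165346	0.203291	6.093525e-01	8.312240e-01	8.469153e-01	ok
rs12	1	12000	A	B	100	0.19	0.0541285	0.197852	0.0459224	0.195129	0.374338	0.192726	0.192453	0.182922	0.203257	7.785145e-01	6.551967e-02	1.695061e-01	ok
rs13	1	13000	A	B	100	0.145	-0.0779838	0.194189	-0.00449742	0.200357	0.273108	0.196411	0.181835	0.168955	0.181189	6.680165e-01	1.317314e-01	2.823598e-01	ok
rs14	1	14000	A	B	100	0.24	-0.0654032	0.178645	-0.0976836	0.179792	0.215053	0.166865	0.177772	0.183407	0.19302	7.129448e-01	2.652148e-01	4.839888e-01	ok
rs15	1	15000	A	B	100	0.245	-0.00818125	0.148375	-0.0073598	0.149163	-0.0293585	0.140088	0.144353	0.143235	0.159543	9.548038e-01	8.540007e-01	9.831595e-01	ok
rs16	1	16000	A	B	100	0.225	-0.107769	0.173726	-0.0981136	0.178197	-0.0437016	0.162071	0.169889	0.172721	0.176215	5.258543e-01	8.041328e-01	7.973462e-01	ok
rs17	1	17000	A	B	100	0.375	-0.0363988	0.155386	-0.0349116	0.15644	-0.0255692	0.157265	0.14163	0.140729	0.183306	7.971792e-01	8.890639e-01	9.614152e-01	ok
rs18	1	18000	A	B	100	0.365	-0.148001	0.125557	-0.163871	0.127345	0.101105	0.126399	0.128305	0.120848	0.207829	2.487014e-01	6.266264e-01	3.305709e-01	ok
rs19	1	19000	A	B	100	0.36	0.156142	0.155721	0.159814	0.154907	0.234241	0.163631	0.159741	0.158015	0.201005	3.283354e-01	2.438779e-01	4.168145e-01	ok
rs20	1	20000	A	B	100	0.44	-0.140631	0.142677	-0.131989	0.140356	0.2768	0.133152	0.139309	0.135418	0.169734	3.127385e-01	1.029356e-01	1.647957e-01	ok
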