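# Published benchmark metric panels for miRNA-target prediction methods.
# One row per method per evaluation: cv_trA = 10-fold CV on the trA energy-
# stratified set (2588 positives / 2588 negatives); fs_trA = feature-selection
# comparison on trA; fs_independent and independent = the held-out test set
# (1248 positives / 241 negatives). Cells print 4 decimals; "null" marks a
# metric that cannot be computed (no positive call: TP + FP = 0).
# mcc_consistent = 0 flags one row whose printed MCC and MCC' disagree
# arithmetically (a typo in the source table); its CHL coheres with MCC'.
table	method	n_pos	n_neg	sn	sp	acc	f1	mcc	mcc_prime	chl	mcc_consistent
cv_trA	ensemble_cv	2588	2588	0.9992	0.9981	0.9986	0.9986	0.9973	0.9986	0.9986	1
cv_trA	RNA22	2588	2588	0.7608	0.8798	0.8203	0.8090	0.6452	0.8226	0.8172	1
cv_trA	miRanda_0_0	2588	2588	0.1967	0.9691	0.5828	0.3204	0.2610	0.6305	0.4671	1
cv_trA	miRanda_0_C	2588	2588	0.0568	0.9903	0.5235	0.1065	0.1315	0.5657	0.2296	1
cv_trA	miRanda_S_0	2588	2588	0.1298	0.9896	0.5596	0.2277	0.2337	0.6169	0.3846	1
cv_trA	miRanda_S_C	2588	2588	0.0479	0.9934	0.5206	0.0909	0.1270	0.5635	0.2041	1
cv_trA	STMDB_3US	2588	2588	0.2434	1.0000	0.6216	0.3915	0.3722	0.6861	0.5338	1
cv_trA	STMDB_3ULS	2588	2588	0.4552	0.7248	0.5900	0.5261	0.1869	0.5934	0.5681	1
cv_trA	STMDB_CS	2588	2588	0.0000	1.0000	0.4999	null	0.0000	0.5000	null	1
cv_trA	STMDB_CLS	2588	2588	0.4892	0.5226	0.5059	0.4975	0.0118	0.5059	0.5031	1
cv_trA	STMDB_5US	2588	2588	0.0228	1.0000	0.5113	0.0446	0.1074	0.5537	0.1145	1
cv_trA	STMDB_5ULS	2588	2588	0.4451	0.4863	0.4657	0.4545	-0.0686	0.4657	0.4619	1
cv_trA	TargetScan	2588	2588	0.9668	0.9084	0.9376	0.9394	0.8767	0.9383	0.9384	1
cv_trA	DIANA_microT	2588	2588	0.2832	0.9988	0.6410	0.4410	0.4038	0.7019	0.5712	1
cv_trA	PITA	2588	2588	0.0978	0.9888	0.5432	0.1763	0.1906	0.5953	0.3263	1
cv_trA	TarPmiR	2588	2588	0.9610	0.9157	0.9384	0.9397	0.8776	0.9388	0.9390	1
cv_trA	MBSTAR	2588	2588	0.2902	0.7101	0.5001	0.3673	0.0003	0.5002	0.4463	1
cv_trA	PACCMIT-CDS	2588	2588	0.0761	0.9992	0.5376	0.1414	0.1959	0.5980	0.2829	1
fs_trA	ensemble	2588	2588	0.9992	0.9981	0.9986	0.9986	0.9973	0.9986	0.9986	1
fs_trA	ensemble_FS_mRMR	2588	2588	1.0000	0.9981	0.9990	0.9990	0.9981	0.9990	0.9990	1
fs_trA	ensemble_FS_CVAE	2588	2588	1.0000	0.9977	0.9988	0.9988	0.9977	0.9988	0.9988	1
fs_independent	ensemble	1248	241	0.7765	0.4066	0.7180	0.8226	0.1538	0.5769	0.6910	1
fs_independent	ensemble_FS_mRMR	1248	241	0.8840	0.2900	0.7900	0.8760	0.1810	0.5905	0.7316	1
fs_independent	ensemble_FS_CVAE	1248	241	0.9354	0.1411	0.8098	0.8923	0.1480	0.5524	0.7201	0
independent	ensemble	1248	241	0.8840	0.2900	0.7900	0.8760	0.1810	0.5905	0.7316	1
independent	RNA22	1248	241	0.3917	0.7593	0.4498	0.5453	0.1143	0.5571	0.5127	1
independent	miRanda_0_0	1248	241	0.0109	0.9959	0.1666	0.0216	0.0250	0.5125	0.0552	1
independent	miRanda_0_C	1248	241	0.4517	0.6141	0.4774	0.5927	0.0484	0.5242	0.5273	1
independent	miRanda_S_0	1248	241	0.0093	1.0000	0.1659	0.0185	0.0386	0.5193	0.0484	1
independent	miRanda_S_C	1248	241	0.4540	0.6058	0.4780	0.5943	0.0439	0.5220	0.5272	1
independent	STMDB_3US	1248	241	0.3419	0.7303	0.4033	0.4911	0.0560	0.5280	0.4680	1
independent	STMDB_3ULS	1248	241	0.6168	0.5394	0.6046	0.7243	0.1160	0.5580	0.6215	1
independent	STMDB_CS	1248	241	0.3084	0.7925	0.3849	0.4578	0.0809	0.5405	0.4523	1
independent	STMDB_CLS	1248	241	0.6589	0.5104	0.6354	0.7527	0.1280	0.5640	0.6417	1
independent	STMDB_5US	1248	241	0.0312	0.9834	0.1816	0.0602	0.0317	0.5159	0.1248	1
independent	STMDB_5ULS	1248	241	0.6098	0.4938	0.5915	0.7154	0.0769	0.5385	0.6066	1
independent	TargetScan	1248	241	0.5397	0.6307	0.5541	0.6709	0.1244	0.5622	0.5912	1
independent	DIANA_microT	1248	241	0.3076	0.7054	0.3705	0.4514	0.0103	0.5052	0.4352	1
independent	PITA	1248	241	0.0522	0.9876	0.2000	0.0990	0.0693	0.5346	0.1767	1
independent	TarPmiR	1248	241	0.7048	0.4896	0.6708	0.7829	0.1513	0.5757	0.6659	1
independent	MBSTAR	1248	241	0.3512	1.0000	0.4538	0.5199	0.2807	0.6404	0.5273	1
independent	PACCMIT-CDS	1248	241	0.0639	0.9461	0.2033	0.1189	0.0150	0.5075	0.1961	1
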