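doc_id	concept_id
doc-000001	G01
doc-000001	G02
doc-000001	N0001
doc-000001	P0001
doc-000002	C00001
doc-000002	C00002
doc-000002	G01
doc-000002	N0001
doc-000002	P0002
doc-000002	P0004
doc-000003	C00001
doc-000003	C00002
doc-000003	D001
doc-000003	N0001
doc-000004	C00002
doc-000004	G01
doc-000004	G02
doc-000004	N0001
doc-000004	P0002
doc-000004	P0004
doc-000005	C00002
doc-000005	N0001
doc-000005	P0003
doc-000005	P0004
doc-000006	C00001
doc-000006	G01
doc-000006	G02
doc-000006	G03
doc-000006	N0001
doc-000007	D001
doc-000007	D002
doc-000007	G03
doc-000007	P0002
doc-000008	C00002
doc-000008	G01
doc-000008	G03
doc-000008	N0001
doc-000008	P0003
doc-000009	C00002
doc-000009	G01
doc-000009	N0001
doc-000009	P0002
doc-000009	P0003
doc-000010	G01
doc-000010	G02
doc-000010	N0001
doc-000010	P0002
doc-000010	P0003
doc-000011	D001
doc-000011	D002
doc-000011	N0001
doc-000011	P0003
doc-000012	G01
doc-000012	N0001
doc-000012	P0002
doc-000013	G01
doc-000013	G03
doc-000013	N0001
doc-000013	P0002
doc-000013	P0003
doc-000014	C00002
doc-000014	G02
doc-000014	N0001
doc-000014	P0002
doc-000015	C00001
doc-000015	G01
doc-000015	N0001
doc-000016	C00001
doc-000016	C00002
doc-000016	G01
doc-000016	N0001
doc-000016	P0002
doc-000016	P0004
doc-000017	D001
doc-000017	G01
doc-000017	G02
doc-000017	N0001
doc-000017	P0002
doc-000018	C00001
doc-000018	G01
doc-000018	G03
doc-000018	N0001
doc-000018	P0002
doc-000019	C00002
doc-000019	G01
doc-000019	G02
doc-000019	N0001
doc-000019	P0002
doc-000020	D001
doc-000020	N0001
doc-000020	P0002
doc-000021	G01
doc-000021	G03
doc-000021	N0001
doc-000021	P0003
doc-000022	G01
doc-000022	G02
doc-000022	N0001
doc-000022	P0003
doc-000023	G01
doc-000023	G02
doc-000023	N0001
doc-000023	P0002
doc-000023	P0004
doc-000024	C00002
doc-000024	G01
doc-000024	N0001
doc-000024	P0002
doc-000025	D002
doc-000025	G01
doc-000025	N0001
doc-000025	P0004
doc-000026	D001
doc-000026	G02
doc-000026	N0001
doc-000027	D002
doc-000027	G01
doc-000027	N0001
doc-000027	P0003
doc-000028	N0001
doc-000028	P0003
doc-000029	N0001
doc-000029	P0001
doc-000030	D001
doc-000030	G01
doc-000030	G02
doc-000030	N0001
doc-000031	C00001
doc-000031	G01
doc-000031	G02
doc-000031	N0001
doc-000031	P0002
doc-000032	C00001
doc-000032	G01
doc-000032	G02
doc-000032	G03
doc-000032	N0001
doc-000032	P0002
doc-000032	P0003
doc-000033	C00002
doc-000033	D001
doc-000033	G01
doc-000033	G02
doc-000033	N0001
doc-000033	P0002
doc-000034	G01
doc-000034	G02
doc-000034	N0001
doc-000034	P0002
doc-000035	D001
doc-000035	N0001
doc-000035	P0002
doc-000036	C00001
doc-000036	C00002
doc-000036	D001
doc-000036	G01
doc-000036	G02
doc-000036	N0001
doc-000036	P0002
doc-000037	C00002
doc-000037	D002
doc-000037	N0001
doc-000037	P0001
doc-000038	G01
doc-000038	G03
doc-000038	N0001
doc-000038	P0001
doc-000039	G01
doc-000039	N0001
doc-000039	P0002
doc-000039	P0003
doc-000040	C00001
doc-000040	C00002
doc-000040	G01
doc-000040	P0002
doc-000040	P0003
doc-000041	C00001
doc-000041	D001
doc-000041	D002
doc-000041	G02
doc-000041	N0001
doc-000042	C00001
doc-000042	G01
doc-000042	N0001
doc-000043	G01
doc-000043	N0001
doc-000043	P0002
doc-000044	D001
doc-000044	D002
doc-000044	N0001
doc-000045	D001
doc-000045	D002
doc-000045	G01
doc-000045	N0001
doc-000045	P0001
doc-000045	P0002
doc-000046	C00001
doc-000046	N0001
doc-000046	P0002
doc-000046	P0004
doc-000047	G01
doc-000047	N0001
doc-000047	P0002
doc-000048	D001
doc-000048	G01
doc-000048	G02
doc-000048	G03
doc-000048	N0001
doc-000048	P0002
doc-000049	G01
doc-000049	N0001
doc-000049	P0003
doc-000050	C00001
doc-000050	D001
doc-000050	G02
doc-000050	G03
doc-000050	N0001
doc-000050	P0002
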