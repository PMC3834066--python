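{"doc_id": "doc-000001", "concepts": ["G01", "G02", "N0001", "P0001"]}
{"doc_id": "doc-000002", "concepts": ["C00001", "C00002", "G01", "N0001", "P0002", "P0004"]}
{"doc_id": "doc-000003", "concepts": ["C00001", "C00002", "D001", "N0001"]}
{"doc_id": "doc-000004", "concepts": ["C00002", "G01", "G02", "N0001", "P0002", "P0004"]}
{"doc_id": "doc-000005", "concepts": ["C00002", "N0001", "P0003", "P0004"]}
{"doc_id": "doc-000006", "concepts": ["C00001", "G01", "G02", "G03", "N0001"]}
{"doc_id": "doc-000007", "concepts": ["D001", "D002", "G03", "P0002"]}
{"doc_id": "doc-000008", "concepts": ["C00002", "G01", "G03", "N0001", "P0003"]}
{"doc_id": "doc-000009", "concepts": ["C00002", "G01", "N0001", "P0002", "P0003"]}
{"doc_id": "doc-000010", "concepts": ["G01", "G02", "N0001", "P0002", "P0003"]}
{"doc_id": "doc-000011", "concepts": ["D001", "D002", "N0001", "P0003"]}
{"doc_id": "doc-000012", "concepts": ["G01", "N0001", "P0002"]}
{"doc_id": "doc-000013", "concepts": ["G01", "G03", "N0001", "P0002", "P0003"]}
{"doc_id": "doc-000014", "concepts": ["C00002", "G02", "N0001", "P0002"]}
{"doc_id": "doc-000015", "concepts": ["C00001", "G01", "N0001"]}
{"doc_id": "doc-000016", "concepts": ["C00001", "C00002", "G01", "N0001", "P0002", "P0004"]}
{"doc_id": "doc-000017", "concepts": ["D001", "G01", "G02", "N0001", "P0002"]}
{"doc_id": "doc-000018", "concepts": ["C00001", "G01", "G03", "N0001", "P0002"]}
{"doc_id": "doc-000019", "concepts": ["C00002", "G01", "G02", "N0001", "P0002"]}
{"doc_id": "doc-000020", "concepts": ["D001", "N0001", "P0002"]}
{"doc_id": "doc-000021", "concepts": ["G01", "G03", "N0001", "P0003"]}
{"doc_id": "doc-000022", "concepts": ["G01", "G02", "N0001", "P0003"]}
{"doc_id": "doc-000023", "concepts": ["G01", "G02", "N0001", "P0002", "P0004"]}
{"doc_id": "doc-000024", "concepts": ["C00002", "G01", "N0001", "P0002"]}
{"doc_id": "doc-000025", "concepts": ["D002", "G01", "N0001", "P0004"]}
{"doc_id": "doc-000026", "concepts": ["D001", "G02", "N0001"]}
{"doc_id": "doc-000027", "concepts": ["D002", "G01", "N0001", "P0003"]}
{"doc_id": "doc-000028", "concepts": ["N0001", "P0003"]}
{"doc_id": "doc-000029", "concepts": ["N0001", "P0001"]}
{"doc_id": "doc-000030", "concepts": ["D001", "G01", "G02", "N0001"]}
{"doc_id": "doc-000031", "concepts": ["C00001", "G01", "G02", "N0001", "P0002"]}
{"doc_id": "doc-000032", "concepts": ["C00001", "G01", "G02", "G03", "N0001", "P0002", "P0003"]}
{"doc_id": "doc-000033", "concepts": ["C00002", "D001", "G01", "G02", "N0001", "P0002"]}
{"doc_id": "doc-000034", "concepts": ["G01", "G02", "N0001", "P0002"]}
{"doc_id": "doc-000035", "concepts": ["D001", "N0001", "P0002"]}
{"doc_id": "doc-000036", "concepts": ["C00001", "C00002", "D001", "G01", "G02", "N0001", "P0002"]}
{"doc_id": "doc-000037", "concepts": ["C00002", "D002", "N0001", "P0001"]}
{"doc_id": "doc-000038", "concepts": ["G01", "G03", "N0001", "P0001"]}
{"doc_id": "doc-000039", "concepts": ["G01", "N0001", "P0002", "P0003"]}
{"doc_id": "doc-000040", "concepts": ["C00001", "C00002", "G01", "P0002", "P0003"]}
{"doc_id": "doc-000041", "concepts": ["C00001", "D001", "D002", "G02", "N0001"]}
{"doc_id": "doc-000042", "concepts": ["C00001", "G01", "N0001"]}
{"doc_id": "doc-000043", "concepts": ["G01", "N0001", "P0002"]}
{"doc_id": "doc-000044", "concepts": ["D001", "D002", "N0001"]}
{"doc_id": "doc-000045", "concepts": ["D001", "D002", "G01", "N0001", "P0001", "P0002"]}
{"doc_id": "doc-000046", "concepts": ["C00001", "N0001", "P0002", "P0004"]}
{"doc_id": "doc-000047", "concepts": ["G01", "N0001", "P0002"]}
{"doc_id": "doc-000048", "concepts": ["D001", "G01", "G02", "G03", "N0001", "P0002"]}
{"doc_id": "doc-000049", "concepts": ["G01", "N0001", "P0003"]}
{"doc_id": "doc-000050", "concepts": ["C00001", "D001", "G02", "G03", "N0001", "P0002"]}
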