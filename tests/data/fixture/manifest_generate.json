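{
  "config_hash": "7a9d59c29d02d479",
  "inputs": {},
  "outputs": {
    "benchmark_gene_disease.tsv": 5,
    "benchmark_ppi.tsv": 6,
    "corpus.jsonl": 50,
    "corpus.tsv": 219,
    "thesaurus.tsv": 13
  },
  "seed": 7,
  "stage": "generate"
}
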