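{
  "name": "5FU-GC-2pair",
  "note": "Published two-pair REO signature for 5-FU-treated gastric cancer: a sample is high risk iff KCNE2 is expressed below both PRPF3 and API5.",
  "pairs": [
    {"gene_a": "KCNE2", "gene_b": "PRPF3", "high_risk_order": "a<b"},
    {"gene_a": "KCNE2", "gene_b": "API5", "high_risk_order": "a<b"}
  ]
}
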