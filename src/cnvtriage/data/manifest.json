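{
  "curated_regions.tsv": "25bd9ba473c57440f90f578b34d08236aad3083e1655c394b63ed24655149101",
  "table1_cnvs.tsv": "6fd9223d19d8dc919efac5df77586eef160161479685cc358654487a84f4b87c",
  "table1_controls.tsv": "8b5723c3a367ecd2070c8d4b1b595c05b904f2335ddb989e03fcf0fe5b892495",
  "table1_genes.tsv": "14015ea7034a906364a3b444e4273111a0de5a73fd23140b5b015f6d2c7293b8"
}
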