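{
  "type": "object",
  "required": ["records", "warnings"],
  "properties": {
    "records": {
      "type": "object",
      "valueSchema": {
        "type": "object",
        "required": [
          "record_id",
          "length_bp",
          "gene_counts",
          "strand_census",
          "composition",
          "codon_inventory"
        ],
        "properties": {
          "record_id": {"type": "string"},
          "species": {"type": "string"},
          "length_bp": {"type": "integer"},
          "gene_counts": {"type": "object"},
          "n_genes": {"type": "integer"},
          "strand_census": {
            "type": "object",
            "required": ["J", "N"]
          },
          "gene_order": {"type": "array"},
          "composition": {
            "type": "object",
            "required": ["whole_genome"]
          },
          "codon_inventory": {"type": "array"},
          "rscu": {"type": "object"},
          "CR1": {"type": "object"},
          "CR2": {"type": "object"}
        }
      }
    },
    "warnings": {"type": "array"},
    "average_composition": {"type": "object"},
    "p_distance": {"type": "object"},
    "nj_tree": {"type": "string"}
  }
}
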