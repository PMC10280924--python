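{
  "description": "Published circRNA catalog summary from a sheep ovary fecundity screen (two breeds, 3+3 ovaries): category counts of the five genomic-origin classes and the length statistics of the full catalog.",
  "category_counts": {
    "sense_overlapping": 8970,
    "intergenic": 356,
    "exonic": 316,
    "antisense": 151,
    "intronic": 85
  },
  "length_stats": {
    "count": 9878,
    "count_ge_200": 9493,
    "count_ge_500": 5706,
    "count_ge_1000": 2574,
    "n50": 22543,
    "total_length": 23522667,
    "max_length": 99455,
    "min_length": 57
  },
  "correlation_samples": 6
}
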