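{
  "description": "Published reference rankings of the 64 codons by influence on five-way kingdom prediction, one from lasso regularization-path survival counts and one from random-forest impurity importance, both fit on the ~13k-organism CUTG-derived codon usage table. Most-influential first. Shipped as the default 'consensus' codon subset source for ORF screening.",
  "lasso": [
    "CUA", "GAU", "AUU", "GCG", "UUC", "AUC", "UGA", "AAU", "CUU", "GGA",
    "UUU", "GAC", "CUC", "AAG", "UUA", "ACA", "CGC", "AGA", "AGG", "CUG",
    "UGC", "AAA", "GAG", "CCG", "ACG", "UCC", "GUU", "AGC", "GCA", "GUA",
    "UUG", "GCU", "CAA", "UGG", "ACU", "GGU", "GGG", "CGA", "UAU", "GGC",
    "CCC", "UCU", "ACC", "UCA", "AUA", "GCC", "GUG", "CCU", "GUC", "UCG",
    "GAA", "AUG", "CAU", "CGG", "UAC", "UAA", "CGU", "UGU", "UAG", "AAC",
    "CCA", "AGU", "CAC", "CAG"
  ],
  "random_forest": [
    "UGA", "AGG", "CUA", "AAG", "UGU", "GCG", "GAU", "CUG", "GAA", "GAG",
    "CUU", "UGC", "ACA", "AGA", "UGG", "CGC", "UCU", "CAG", "AUA", "AAA",
    "GGC", "UUC", "UUA", "CCG", "ACU", "CGA", "GAC", "CCC", "CGU", "CCA",
    "AUG", "GGA", "GGU", "UUG", "AUU", "CCU", "AGC", "UCC", "AUC", "GGG",
    "GUA", "ACG", "GCU", "CUC", "UUU", "UCG", "GCA", "CAU", "CGG", "CAA",
    "UCA", "UAU", "GUU", "AAC", "UAA", "UAC", "GUG", "GCC", "GUC", "AGU",
    "AAU", "ACC", "CAC", "UAG"
  ]
}
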