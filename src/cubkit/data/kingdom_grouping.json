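{
  "description": "Default collapse of CUTG/GenBank division codes into the 5-way kingdom scheme used for classification: arc (archaea), bct (bacteria), euk (eukaryote), phg (bacteriophage), vrl (virus). All eukaryotic divisions (primate, rodent, mammal, other vertebrate, invertebrate, plant, fungus) map to euk. Codes absent from the map (e.g. plm, plasmid) are dropped by the loader.",
  "mapping": {
    "arc": "arc",
    "bct": "bct",
    "phg": "phg",
    "vrl": "vrl",
    "pri": "euk",
    "rod": "euk",
    "mam": "euk",
    "vrt": "euk",
    "inv": "euk",
    "pln": "euk",
    "fng": "euk",
    "euk": "euk"
  }
}
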