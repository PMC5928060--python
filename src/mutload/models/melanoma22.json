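{
  "name": "melanoma22",
  "cancer_type": "melanoma",
  "description": "Published 22-gene melanoma mutation load estimation model (training: TCGA SKCM, n=333).",
  "intercept": 18.17,
  "genes": [
    {"symbol": "TNXB", "entrez_id": 7148, "weight": 93.24},
    {"symbol": "NPAP1", "entrez_id": 23742, "weight": 80.88},
    {"symbol": "DNAH10", "entrez_id": 196385, "weight": 75.59},
    {"symbol": "ADGRG4", "entrez_id": 139378, "weight": 69.31},
    {"symbol": "SCN10A", "entrez_id": 6336, "weight": 58.65},
    {"symbol": "CMYA5", "entrez_id": 202333, "weight": 55.98},
    {"symbol": "FAT3", "entrez_id": 120114, "weight": 54.53},
    {"symbol": "ZNF831", "entrez_id": 128611, "weight": 53.47},
    {"symbol": "CSMD3", "entrez_id": 114788, "weight": 53.14},
    {"symbol": "MYH4", "entrez_id": 4622, "weight": 52.94},
    {"symbol": "PKHD1L1", "entrez_id": 93035, "weight": 51.74},
    {"symbol": "RYR2", "entrez_id": 6262, "weight": 50.95},
    {"symbol": "LRP2", "entrez_id": 4036, "weight": 49.34},
    {"symbol": "COL4A4", "entrez_id": 1286, "weight": 41.92},
    {"symbol": "RP1", "entrez_id": 6101, "weight": 40.24},
    {"symbol": "APOB", "entrez_id": 338, "weight": 38.24},
    {"symbol": "UNC13C", "entrez_id": 440279, "weight": 36.52},
    {"symbol": "XIRP2", "entrez_id": 129446, "weight": 35.84},
    {"symbol": "MXRA5", "entrez_id": 25878, "weight": 33.81},
    {"symbol": "DNAH11", "entrez_id": 8701, "weight": 30.16},
    {"symbol": "MUC17", "entrez_id": 140453, "weight": 28.28},
    {"symbol": "DNAH9", "entrez_id": 1770, "weight": 27.21}
  ]
}
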