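{
  "name": "luad24",
  "cancer_type": "lung adenocarcinoma",
  "description": "Published 24-gene lung adenocarcinoma mutation load estimation model (training: TCGA LUAD, n=230).",
  "intercept": 47.24,
  "genes": [
    {"symbol": "PXDNL", "entrez_id": 137902, "weight": 68.72},
    {"symbol": "NOTCH4", "entrez_id": 4855, "weight": 64.27},
    {"symbol": "CSMD2", "entrez_id": 114784, "weight": 58.51},
    {"symbol": "PLPPR4", "entrez_id": 9890, "weight": 54.54},
    {"symbol": "NRXN1", "entrez_id": 9378, "weight": 50.57},
    {"symbol": "KMT2C", "entrez_id": 58508, "weight": 49.19},
    {"symbol": "ADAMTS12", "entrez_id": 81792, "weight": 46.68},
    {"symbol": "COL6A3", "entrez_id": 1293, "weight": 45.95},
    {"symbol": "ZNF831", "entrez_id": 128611, "weight": 41.88},
    {"symbol": "FAM135B", "entrez_id": 51059, "weight": 41.01},
    {"symbol": "FLG", "entrez_id": 2312, "weight": 40.99},
    {"symbol": "FAM47C", "entrez_id": 442444, "weight": 40.62},
    {"symbol": "ASXL3", "entrez_id": 80816, "weight": 39.52},
    {"symbol": "ERICH3", "entrez_id": 127254, "weight": 37.88},
    {"symbol": "HRNR", "entrez_id": 388697, "weight": 37.14},
    {"symbol": "LRP2", "entrez_id": 4036, "weight": 36.12},
    {"symbol": "ASTN1", "entrez_id": 460, "weight": 35.65},
    {"symbol": "RYR3", "entrez_id": 6263, "weight": 35.57},
    {"symbol": "MXRA5", "entrez_id": 25878, "weight": 34.54},
    {"symbol": "ADGRG4", "entrez_id": 139378, "weight": 31.22},
    {"symbol": "NALCN", "entrez_id": 259232, "weight": 29.79},
    {"symbol": "LRP1B", "entrez_id": 53353, "weight": 28.99},
    {"symbol": "PAPPA2", "entrez_id": 60676, "weight": 27.10},
    {"symbol": "ZFHX4", "entrez_id": 79776, "weight": 22.57}
  ]
}
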