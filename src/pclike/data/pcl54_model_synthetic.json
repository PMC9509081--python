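{
 "provenance": "packaged_table2",
 "threshold": 3.55,
 "metadata": {
  "description": "Synthetic stand-in for the published 54-gene PCL-like classifier: gene identities combine CTC-associated genes named in the study's prose with SYNPCL placeholder identifiers; the published table itself is not machine-readable here. Threshold 3.55 with the inclusive >= rule. Weights are equal by default; the schema accepts per-gene real weights. Standardization statistics must come from a user-declared reference cohort.",
  "gene_dialect": "HGNC symbols per Ensembl release 74",
  "synthetic": true
 },
 "genes": [
  {
   "gene_id": "MKI67",
   "sign": 1,
   "weight": 1.0
  },
  {
   "gene_id": "MCM2",
   "sign": 1,
   "weight": 1.0
  },
  {
   "gene_id": "CENPM",
   "sign": 1,
   "weight": 1.0
  },
  {
   "gene_id": "SRSF10",
   "sign": 1,
   "weight": 1.0
  },
  {
   "gene_id": "SF3A2",
   "sign": 1,
   "weight": 1.0
  },
  {
   "gene_id": "PUF60",
   "sign": 1,
   "weight": 1.0
  },
  {
   "gene_id": "XPO1",
   "sign": 1,
   "weight": 1.0
  },
  {
   "gene_id": "PHF19",
   "sign": 1,
   "weight": 1.0
  },
  {
   "gene_id": "DCK",
   "sign": 1,
   "weight": 1.0
  },
  {
   "gene_id": "CHEK1",
   "sign": 1,
   "weight": 1.0
  },
  {
   "gene_id": "DOCK11",
   "sign": 1,
   "weight": 1.0
  },
  {
   "gene_id": "NCAM1",
   "sign": -1,
   "weight": 1.0
  },
  {
   "gene_id": "ITGA6",
   "sign": -1,
   "weight": 1.0
  },
  {
   "gene_id": "SDC1",
   "sign": -1,
   "weight": 1.0
  },
  {
   "gene_id": "PTEN",
   "sign": -1,
   "weight": 1.0
  },
  {
   "gene_id": "TUSC2",
   "sign": -1,
   "weight": 1.0
  },
  {
   "gene_id": "TAGLN2",
   "sign": -1,
   "weight": 1.0
  },
  {
   "gene_id": "ROCK1",
   "sign": -1,
   "weight": 1.0
  },
  {
   "gene_id": "DLC1",
   "sign": -1,
   "weight": 1.0
  },
  {
   "gene_id": "DCLRE1C",
   "sign": -1,
   "weight": 1.0
  },
  {
   "gene_id": "SLFN11",
   "sign": -1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL022",
   "sign": -1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL023",
   "sign": 1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL024",
   "sign": -1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL025",
   "sign": 1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL026",
   "sign": -1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL027",
   "sign": 1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL028",
   "sign": -1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL029",
   "sign": 1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL030",
   "sign": -1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL031",
   "sign": 1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL032",
   "sign": -1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL033",
   "sign": 1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL034",
   "sign": -1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL035",
   "sign": 1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL036",
   "sign": -1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL037",
   "sign": 1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL038",
   "sign": -1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL039",
   "sign": 1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL040",
   "sign": -1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL041",
   "sign": 1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL042",
   "sign": -1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL043",
   "sign": 1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL044",
   "sign": -1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL045",
   "sign": 1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL046",
   "sign": -1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL047",
   "sign": 1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL048",
   "sign": -1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL049",
   "sign": 1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL050",
   "sign": -1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL051",
   "sign": 1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL052",
   "sign": -1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL053",
   "sign": 1,
   "weight": 1.0
  },
  {
   "gene_id": "SYNPCL054",
   "sign": -1,
   "weight": 1.0
  }
 ]
}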