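{
 "description": "Features with repeat-scan CoV > 10% in >= 1 Revolver insert. n_inserts (how many of the three insert sizes failed) is layout-inferred from a flattened three-column table and is descriptive only; membership is what the reduction replay uses.",
 "tc99m": [
  {
   "feature": "Discretised histogram Excess Kurtosis",
   "n_inserts": 1
  },
  {
   "feature": "SUV Excess Kurtosis",
   "n_inserts": 1
  },
  {
   "feature": "GLZLM SZLGE",
   "n_inserts": 1
  },
  {
   "feature": "Discretised histogram Excess Kurtosis",
   "n_inserts": 2
  },
  {
   "feature": "GLZLM LZLGE",
   "n_inserts": 2
  },
  {
   "feature": "GLZLM ZLNU",
   "n_inserts": 2
  },
  {
   "feature": "GLZLM LZE",
   "n_inserts": 3
  },
  {
   "feature": "GLZLM SZHGE",
   "n_inserts": 3
  },
  {
   "feature": "NGLDM Busyness",
   "n_inserts": 3
  }
 ],
 "lu177": [
  {
   "feature": "Compacity",
   "n_inserts": 1
  },
  {
   "feature": "Discretised SUV Kurtosis",
   "n_inserts": 1
  },
  {
   "feature": "Discretised SUV Skewness",
   "n_inserts": 1
  },
  {
   "feature": "Discretised SUVmin",
   "n_inserts": 1
  },
  {
   "feature": "GLCM contrast",
   "n_inserts": 1
  },
  {
   "feature": "GLZLM LGZE",
   "n_inserts": 1
  },
  {
   "feature": "SUVmin",
   "n_inserts": 1
  },
  {
   "feature": "GLRLM LRLGE",
   "n_inserts": 1
  },
  {
   "feature": "GLZLM SZHGE",
   "n_inserts": 1
  },
  {
   "feature": "GLZLM ZLNU",
   "n_inserts": 1
  },
  {
   "feature": "SUV Excess Kurtosis",
   "n_inserts": 1
  },
  {
   "feature": "Discretised histogram Kurtosis",
   "n_inserts": 2
  },
  {
   "feature": "GLZLM SZE",
   "n_inserts": 2
  },
  {
   "feature": "GLZLM SZHGE",
   "n_inserts": 2
  },
  {
   "feature": "GLZLM ZP",
   "n_inserts": 2
  },
  {
   "feature": "NGLDM Busyness",
   "n_inserts": 2
  },
  {
   "feature": "NGLDM Contrast",
   "n_inserts": 2
  },
  {
   "feature": "GLZLM LZLGE",
   "n_inserts": 2
  },
  {
   "feature": "GLRLM SRLGE",
   "n_inserts": 2
  },
  {
   "feature": "SUV Skewness",
   "n_inserts": 2
  },
  {
   "feature": "Discretised histogram Excess Kurtosis",
   "n_inserts": 3
  },
  {
   "feature": "Discretised histogram Excess Kurtosis",
   "n_inserts": 3
  },
  {
   "feature": "GLCM energy",
   "n_inserts": 3
  },
  {
   "feature": "GLZLM GLNU",
   "n_inserts": 3
  },
  {
   "feature": "GLZLM HGZE",
   "n_inserts": 3
  },
  {
   "feature": "GLZLM LZE",
   "n_inserts": 3
  },
  {
   "feature": "GLRLM LGRE",
   "n_inserts": 3
  },
  {
   "feature": "SUV Kurtosis",
   "n_inserts": 3
  },
  {
   "feature": "GLZLM SZLGE",
   "n_inserts": 3
  }
 ]
}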