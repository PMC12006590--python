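{
 "description": "Non-converging features on the uniform-phantom volume-dependency screen.",
 "tc99m": [
  "SUVQ1",
  "SUVQ2",
  "SUVQ3",
  "Discretised SUVmean",
  "Discretised SUVmax",
  "Discretised TLSRE",
  "GLCM homogeneity",
  "GLCM contrast",
  "GLCM dissimilarity",
  "GLRLM LGRE",
  "GLRLM HGRE",
  "GLRLM SRLGE",
  "GLRLM GLNU",
  "GLRLM RLNU",
  "NGLDM Contrast",
  "NGLDM Busyness",
  "GLZLM SZE",
  "GLZLM LZE",
  "GLZLM LGZE",
  "GLZLM HGZE",
  "GLZLM SZLGE",
  "GLZLM SZHGE",
  "GLZLM LZLGE",
  "GLZLM LZHGE",
  "GLZLM GLNU",
  "GLZLM ZLNU"
 ],
 "lu177": [
  "SUV Skewness",
  "SUV Kurtosis",
  "SUV Excess Kurtosis",
  "Discretised SUVmin",
  "Discretised SUVmax",
  "Discretised SUVQ3",
  "Discretised SUV Skewness",
  "Discretised SUVpeak 0.5 ml",
  "Discretised SUVpeak 1.0 ml",
  "Discretised TLSRE",
  "GLRLM HGRE",
  "GLRLM GLNU",
  "GLRLM RLNU",
  "NGLDM Busyness",
  "GLZLM SZE",
  "GLZLM LZE",
  "GLZLM LGZE",
  "GLZLM HGZE",
  "GLZLM SZLGE",
  "GLZLM SZHGE",
  "GLZLM LZLGE",
  "GLZLM LZHGE",
  "GLZLM GLNU",
  "GLZLM ZLNU",
  "GLRLM LRE"
 ]
}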