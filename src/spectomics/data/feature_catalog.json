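{
 "version": "1.0",
 "description": "Catalogue of the 67 texture-analysis feature names used by the robustness screen (LIFEx v6.3-style naming). The discretised excess kurtosis appears once, under the histogram family; the alternative spelling 'Discretised SUV Excess Kurtosis' is an alias normalised on table load.",
 "aliases": {
  "Discretised SUV Excess Kurtosis": "Discretised histogram Excess Kurtosis"
 },
 "families": {
  "intensity": [
   "SUVmin",
   "SUVmean",
   "SUVstd",
   "SUVmax",
   "SUVQ1",
   "SUVQ2",
   "SUVQ3",
   "SUV Skewness",
   "SUV Kurtosis",
   "SUV Excess Kurtosis",
   "SUVpeak 0.5 ml",
   "SUVpeak 1.0 ml",
   "TLSRE"
  ],
  "discretised_intensity": [
   "Discretised SUVmin",
   "Discretised SUVmean",
   "Discretised SUVstd",
   "Discretised SUVmax",
   "Discretised SUVQ1",
   "Discretised SUVQ2",
   "Discretised SUVQ3",
   "Discretised SUV Skewness",
   "Discretised SUV Kurtosis",
   "Discretised SUVpeak 0.5 ml",
   "Discretised SUVpeak 1.0 ml",
   "Discretised TLSRE"
  ],
  "histogram": [
   "Discretised histogram Skewness",
   "Discretised histogram Kurtosis",
   "Discretised histogram Excess Kurtosis",
   "Discretised histogram entropy log10",
   "Discretised histogram entropy log2",
   "Discretised histogram energy"
  ],
  "shape": [
   "Volume",
   "Sphericity",
   "Surface area",
   "Compacity"
  ],
  "glcm": [
   "GLCM homogeneity",
   "GLCM energy",
   "GLCM contrast",
   "GLCM correlation",
   "GLCM entropy log10",
   "GLCM entropy log2",
   "GLCM dissimilarity"
  ],
  "glrlm": [
   "GLRLM SRE",
   "GLRLM LRE",
   "GLRLM LGRE",
   "GLRLM HGRE",
   "GLRLM SRLGE",
   "GLRLM SRHGE",
   "GLRLM LRLGE",
   "GLRLM LRHGE",
   "GLRLM GLNU",
   "GLRLM RLNU",
   "GLRLM RP"
  ],
  "ngldm": [
   "NGLDM Coarseness",
   "NGLDM Contrast",
   "NGLDM Busyness"
  ],
  "glzlm": [
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
   "GLZLM ZP"
  ]
 },
 "features": [
  "SUVmin",
  "SUVmean",
  "SUVstd",
  "SUVmax",
  "SUVQ1",
  "SUVQ2",
  "SUVQ3",
  "SUV Skewness",
  "SUV Kurtosis",
  "SUV Excess Kurtosis",
  "SUVpeak 0.5 ml",
  "SUVpeak 1.0 ml",
  "TLSRE",
  "Discretised SUVmin",
  "Discretised SUVmean",
  "Discretised SUVstd",
  "Discretised SUVmax",
  "Discretised SUVQ1",
  "Discretised SUVQ2",
  "Discretised SUVQ3",
  "Discretised SUV Skewness",
  "Discretised SUV Kurtosis",
  "Discretised SUVpeak 0.5 ml",
  "Discretised SUVpeak 1.0 ml",
  "Discretised TLSRE",
  "Discretised histogram Skewness",
  "Discretised histogram Kurtosis",
  "Discretised histogram Excess Kurtosis",
  "Discretised histogram entropy log10",
  "Discretised histogram entropy log2",
  "Discretised histogram energy",
  "Volume",
  "Sphericity",
  "Surface area",
  "Compacity",
  "GLCM homogeneity",
  "GLCM energy",
  "GLCM contrast",
  "GLCM correlation",
  "GLCM entropy log10",
  "GLCM entropy log2",
  "GLCM dissimilarity",
  "GLRLM SRE",
  "GLRLM LRE",
  "GLRLM LGRE",
  "GLRLM HGRE",
  "GLRLM SRLGE",
  "GLRLM SRHGE",
  "GLRLM LRLGE",
  "GLRLM LRHGE",
  "GLRLM GLNU",
  "GLRLM RLNU",
  "GLRLM RP",
  "NGLDM Coarseness",
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
  "GLZLM ZLNU",
  "GLZLM ZP"
 ]
}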