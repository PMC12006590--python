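{
 "description": "Retained feature lists after the combined reduction. The 99mTc entry 'Discretised histogram energy' was dropped by the source text extraction and is reconstructed from the reduction set arithmetic (catalogue minus the two exclusion screens).",
 "tc99m": [
  "Discretised histogram energy",
  "SUVmin",
  "SUVmean",
  "SUVstd",
  "SUVmax",
  "SUV Skewness",
  "SUV Kurtosis",
  "SUVpeak 0.5 ml",
  "SUVpeak 1.0 ml",
  "TLSRE",
  "Discretised SUVmin",
  "Discretised SUVstd",
  "Discretised SUVQ1",
  "Discretised SUVQ2",
  "Discretised SUVQ3",
  "Discretised SUV Skewness",
  "Discretised SUV Kurtosis",
  "Discretised SUVpeak 0.5 ml",
  "Discretised SUVpeak 1.0 ml",
  "Discretised histogram Skewness",
  "Discretised histogram Kurtosis",
  "Discretised histogram entropy log10",
  "Discretised histogram entropy log2",
  "Sphericity",
  "Surface area",
  "Compacity",
  "GLCM energy",
  "GLCM correlation",
  "GLCM entropy log10",
  "GLCM entropy log2",
  "GLRLM SRE",
  "GLRLM LRE",
  "GLRLM SRHGE",
  "GLRLM LRLGE",
  "GLRLM LRHGE",
  "GLRLM RP",
  "NGLDM Coarseness",
  "GLZLM ZP",
  "Volume"
 ],
 "lu177": [
  "SUVmin",
  "SUVmean",
  "SUVstd",
  "SUVmax",
  "SUVQ1",
  "SUVQ2",
  "SUVQ3",
  "SUVpeak 0.5 ml",
  "SUVpeak 1.0 ml",
  "TLSRE",
  "Discretised SUVmean",
  "Discretised SUVstd",
  "Discretised SUVQ1",
  "Discretised SUVQ2",
  "Discretised histogram Skewness",
  "Discretised histogram entropy log10",
  "Discretised histogram entropy log2",
  "Discretised histogram energy",
  "Sphericity",
  "Surface area",
  "GLCM homogeneity",
  "GLCM correlation",
  "GLCM entropy log10",
  "GLCM entropy log2",
  "GLCM dissimilarity",
  "GLRLM SRE",
  "GLRLM SRHGE",
  "GLRLM LRHGE",
  "GLRLM RP",
  "NGLDM Coarseness",
  "NGLDM Contrast",
  "GLZLM ZP",
  "Volume"
 ]
}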