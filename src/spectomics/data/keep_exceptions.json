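{
 "description": "Features exempted from exclusion ('keep list'): volume-correlated or CoV-failing features retained anyway for their established clinical value. Derived as retained-list INTERSECT exclusions.",
 "tc99m": [],
 "lu177": [
  {
   "feature": "SUVmin",
   "note": "SUV statistic in common clinical usage; retained despite a CoV failure."
  },
  {
   "feature": "NGLDM Contrast",
   "note": "retained despite a CoV failure; contrast-type features carry clinical value."
  },
  {
   "feature": "GLZLM ZP",
   "note": "zone percentage retained despite a CoV failure; usable down to small volumes."
  }
 ]
}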