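# Comorbid conditions (Charlson Comorbidity Index classification) and the
# survey variable codes that flag each one, matched on either side of a rule.
conditions:
  cardiovascular_disease: ["x.michd"]
  chronic_pulmonary_disease: ["chccopd1", "x.casthm1"]
  rheumatoid_arthritis: ["x.drdxar1"]
  diabetes: ["diabete3"]
  cancer: ["chcocncr"]
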