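# Annotation rules for BRFSS-style survey variables.
#
# Codes listed here are the condition/comorbidity/behavior variables used by
# the bundled analysis defaults; supply a fuller file for a complete survey
# run. Raw response codes are strings: "1" = yes/present, "2" = no,
# "7" = don't know/not sure, "9" = refused, "" = missing. Calculated
# variables (x.* prefix) follow the same convention.
variables:
  - code: chckidny
    label: "(Ever told) you have kidney disease (not stones/bladder/incontinence)"
  - code: diffwalk
    label: "Serious difficulty walking or climbing stairs"
  - code: diffalon
    label: "Difficulty doing errands alone"
  - code: x.michd
    label: "Ever diagnosed with coronary heart disease or myocardial infarction (calculated)"
  - code: x.casthm1
    label: "Current asthma (calculated)"
  - code: x.rfhype5
    label: "Told blood pressure high (calculated risk factor)"
  - code: x.rfsmok3
    label: "Current smoker (calculated risk factor)"
  - code: x.rfchol1
    label: "Told blood cholesterol high (calculated risk factor)"
  - code: x.drdxar1
    label: "Diagnosed with arthritis (calculated)"
  - code: chccopd1
    label: "(Ever told) you have COPD, emphysema or chronic bronchitis"
  - code: diabete3
    label: "(Ever told) you have diabetes"
  - code: chcocncr
    label: "(Ever told) you had any other type of cancer (non-skin)"
  - code: x.age65yr
    label: "Age 65 or older (calculated)"
    positive: ["2"]      # calculated variable: 1 = 18-64, 2 = 65+
    negative: ["1", "3"]
    missing: [""]
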