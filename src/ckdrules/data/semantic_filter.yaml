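# Semantic filter for predication mining.
#
# semtype codes are UMLS Semantic Network abbreviations. The whitelist keeps
# terms relevant to lifestyle behavior, symptoms and diseases; the six focus
# types define the lifestyle keyword list:
#   dora = daily or recreational activity     food = food
#   hops = hazardous or poisonous substance   inbe = individual behavior
#   mobd = mental or behavioral dysfunction   fndg = finding
# The term blacklist removes generic terms; it is seeded with well-known
# offenders and meant to be extended per corpus (the full list used on a
# real corpus runs to dozens of terms).
semtype_whitelist:
  - dora
  - food
  - hops
  - inbe
  - mobd
  - fndg
  - dsyn   # disease or syndrome
  - sosy   # sign or symptom
  - neop   # neoplastic process
  - phsu   # pharmacologic substance
  - topp   # therapeutic or preventive procedure
  - orch   # organic chemical
  - bacs   # biologically active substance
  - patf   # pathologic function
focus_semtypes: [dora, food, hops, inbe, mobd, fndg]
term_blacklist:
  - patients
  - agent
  - woman
  - child
  - author
  - disease
keep_negated: true
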