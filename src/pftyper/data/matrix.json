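{
 "P. corrugata": {
  "DGPf_0": "+",
  "DGPf_1": "+",
  "DGPf_2": "-",
  "DGPf_3": "-",
  "DGPf_4": "-",
  "DGPf_5": "-",
  "DGPf_6": "-",
  "DGPf_7": "-",
  "DGPf_8": "-"
 },
 "P. koreensis": {
  "DGPf_0": "+",
  "DGPf_1": "-",
  "DGPf_2": "+",
  "DGPf_3": "-",
  "DGPf_4": "-",
  "DGPf_5": "-",
  "DGPf_6": "-",
  "DGPf_7": "-",
  "DGPf_8": "-"
 },
 "P. jessenii": {
  "DGPf_0": "±",
  "DGPf_1": "-",
  "DGPf_2": "+",
  "DGPf_3": "+",
  "DGPf_4": "-",
  "DGPf_5": "-",
  "DGPf_6": "-",
  "DGPf_7": "-",
  "DGPf_8": "-"
 },
 "P. mandelii": {
  "DGPf_0": "+",
  "DGPf_1": "-",
  "DGPf_2": "-",
  "DGPf_3": "+",
  "DGPf_4": "-",
  "DGPf_5": "-",
  "DGPf_6": "-",
  "DGPf_7": "-",
  "DGPf_8": "-"
 },
 "P. gessardii": {
  "DGPf_0": "-",
  "DGPf_1": "-",
  "DGPf_2": "-",
  "DGPf_3": "-",
  "DGPf_4": "-",
  "DGPf_5": "+",
  "DGPf_6": "+",
  "DGPf_7": "-",
  "DGPf_8": "-"
 },
 "P. fluorescens": {
  "DGPf_0": "-",
  "DGPf_1": "-",
  "DGPf_2": "-",
  "DGPf_3": "-",
  "DGPf_4": "-",
  "DGPf_5": "+",
  "DGPf_6": "-",
  "DGPf_7": "+",
  "DGPf_8": "-"
 },
 "P. protegens": {
  "DGPf_0": "±",
  "DGPf_1": "-",
  "DGPf_2": "+",
  "DGPf_3": "-",
  "DGPf_4": "+",
  "DGPf_5": "-",
  "DGPf_6": "±",
  "DGPf_7": "-",
  "DGPf_8": "-"
 },
 "P. chlororaphis": {
  "DGPf_0": "-",
  "DGPf_1": "-",
  "DGPf_2": "+",
  "DGPf_3": "-",
  "DGPf_4": "-",
  "DGPf_5": "-",
  "DGPf_6": "-",
  "DGPf_7": "-",
  "DGPf_8": "+"
 }
}
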