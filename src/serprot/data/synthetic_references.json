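{
 "trypsin": {
  "activation_site": 3,
  "his": 47,
  "asp": 93,
  "ser": 194,
  "s1": 188,
  "cys1": 48,
  "cys2": 64,
  "cys3": 159,
  "cys4": 170,
  "cys5": 205,
  "cys6": 225
 },
 "chymotrypsin": {
  "activation_site": 3,
  "his": 47,
  "asp": 93,
  "ser": 194,
  "s1": 188,
  "cys1": 48,
  "cys2": 64,
  "cys3": 159,
  "cys4": 170,
  "cys5": 205,
  "cys6": 225
 }
}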