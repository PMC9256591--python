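{
 "COI": {
  "BIN": 77,
  "ASAP": 57,
  "PTP": 64,
  "GMYC": 58,
  "KoT=4": 99,
  "KoT=5": 88,
  "PDT": 54
 },
 "16S": {
  "ASAP": 46,
  "PTP": 51,
  "GMYC": 53,
  "KoT=4": 59,
  "KoT=5": 56
 }
}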