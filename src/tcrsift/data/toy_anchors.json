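{
 "v": {
  "TRBV-T1": {
   "cys_start": 105
  },
  "TRBV-T2": {
   "cys_start": 105
  },
  "TRBV-T3": {
   "cys_start": 105
  },
  "TRBV-T4": {
   "cys_start": 105
  }
 },
 "j": {
  "TRBJ-T1": {
   "phe_start": 12
  },
  "TRBJ-T2": {
   "phe_start": 12
  },
  "TRBJ-T3": {
   "phe_start": 12
  }
 }
}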