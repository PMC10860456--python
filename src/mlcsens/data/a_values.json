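{
  "targets": {
    "prostate": -25.0,
    "lung": -20.0,
    "brain_met": -10.0,
    "spine_met": -20.0
  },
  "oars": {
    "rectum": 8.33,
    "bladder": 2.0,
    "normal_lung": 1.15,
    "spinal_cord": 20.0,
    "normal_brain": 4.0
  }
}
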