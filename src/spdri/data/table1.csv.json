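{
 "exposure_columns": {
  "10um": "exposure_ms_10um",
  "20um": "exposure_ms_20um"
 }
}
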