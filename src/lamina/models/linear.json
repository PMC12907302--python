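{
 "name": "linear",
 "kind": "synapse",
 "params": [
  {
   "name": "gain",
   "default": 1.0,
   "unit": "1/s"
  }
 ],
 "output_kind": "voltage_rate",
 "rule": "w*gain*pre_V",
 "protected": false
}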