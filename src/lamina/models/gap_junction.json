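{
 "name": "gap_junction",
 "kind": "synapse",
 "params": [
  {
   "name": "w_gap",
   "default": 10.0,
   "unit": "Hz",
   "min": 0.0
  }
 ],
 "output_kind": "voltage_rate",
 "rule": "-w*w_gap*(post_V - pre_V)",
 "protected": false
}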