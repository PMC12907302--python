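{
 "name": "cortical_rate_delayed",
 "kind": "synapse",
 "params": [
  {
   "name": "gain",
   "default": 1.0,
   "unit": ""
  },
  {
   "name": "conduction_velocity",
   "default": 100.0,
   "unit": "mm/s",
   "min": 0.0
  }
 ],
 "output_kind": "firing_rate",
 "rule": "w*gain*pre_nu",
 "protected": false
}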