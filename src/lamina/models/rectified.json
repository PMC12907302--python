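{
 "name": "rectified",
 "kind": "synapse",
 "params": [
  {
   "name": "gain",
   "default": 1.0,
   "unit": "1/s"
  },
  {
   "name": "theta_pre",
   "default": 0.0,
   "unit": "mV"
  }
 ],
 "output_kind": "voltage_rate",
 "rule": "w*gain*max(pre_V - theta_pre, 0)",
 "protected": false
}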