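{
 "name": "acetylcholine",
 "kind": "synapse",
 "params": [
  {
   "name": "g_A",
   "default": 3.0,
   "unit": "nS",
   "min": 0.0
  },
  {
   "name": "gamma_A",
   "default": 100.0,
   "unit": "nM^2",
   "min": 0.0
  },
  {
   "name": "V_A",
   "default": 0.0,
   "unit": "mV"
  }
 ],
 "output_kind": "current",
 "rule": "-w*g_A*pre_A^2/(gamma_A + pre_A^2)*(post_V - V_A)",
 "protected": false
}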