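{
 "name": "ligand_gated",
 "kind": "synapse",
 "params": [
  {
   "name": "g",
   "default": 1.0,
   "unit": "Hz",
   "min": 0.0
  },
  {
   "name": "E",
   "default": -70.0,
   "unit": "mV"
  },
  {
   "name": "literal",
   "default": 0.0,
   "unit": "",
   "min": 0.0,
   "max": 1.0
  }
 ],
 "output_kind": "voltage_rate",
 "rule": "-w*g*pre_n*(literal*pre_V + (1 - literal)*post_V - E)",
 "protected": false
}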