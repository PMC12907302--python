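{
 "name": "retino_cortical",
 "kind": "synapse",
 "params": [
  {
   "name": "weight",
   "default": 1.0,
   "unit": ""
  },
  {
   "name": "density_retina",
   "default": 400.0,
   "unit": "1/mm^2",
   "min": 0.0
  },
  {
   "name": "density_cortex",
   "default": 4000.0,
   "unit": "1/mm^2",
   "min": 1e-12
  }
 ],
 "output_kind": "firing_rate",
 "rule": "w*weight*(density_retina/density_cortex)*pre_firingRate",
 "protected": false
}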