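{
 "name": "electrode",
 "kind": "cell",
 "state_vars": [
  {
   "name": "V",
   "unit": "mV"
  }
 ],
 "params": [
  {
   "name": "tau",
   "default": 0.01,
   "unit": "s",
   "min": 1e-06
  },
  {
   "name": "C",
   "default": 0.1,
   "unit": "nF",
   "min": 1e-09
  }
 ],
 "input_slots": [
  "external"
 ],
 "aux_functions": {},
 "rhs": {
  "V": "-V/tau + ext/C"
 },
 "outputs": {
  "V": "V"
 },
 "protected": false
}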