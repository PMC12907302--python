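{
 "name": "awc_cell",
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
   "default": 0.05,
   "unit": "s",
   "min": 1e-06
  },
  {
   "name": "g",
   "default": 0.5,
   "unit": "1/mV",
   "min": 0.0
  }
 ],
 "input_slots": [
  "external",
  "synaptic_voltage_rate"
 ],
 "aux_functions": {},
 "rhs": {
  "V": "-V/tau + V_syn + ext"
 },
 "outputs": {
  "V": "V",
  "f": "0.5*(1 + erf(g*V/sqrt(2)))"
 },
 "protected": false
}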