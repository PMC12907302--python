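{
 "name": "linear_cell",
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
   "default": 0.1,
   "unit": "s",
   "min": 1e-06
  },
  {
   "name": "E_L",
   "default": -60.0,
   "unit": "mV"
  }
 ],
 "input_slots": [
  "synaptic_voltage_rate"
 ],
 "aux_functions": {},
 "rhs": {
  "V": "-(V - E_L)/tau + V_syn"
 },
 "outputs": {
  "V": "V"
 },
 "protected": false
}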