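{
 "name": "linear_pharma_cell",
 "kind": "cell",
 "state_vars": [
  {
   "name": "V",
   "unit": "mV"
  }
 ],
 "params": [
  {
   "name": "C",
   "default": 0.1,
   "unit": "nF",
   "min": 1e-09
  },
  {
   "name": "g_L",
   "default": 1.0,
   "unit": "nS",
   "min": 0.0
  },
  {
   "name": "E_L",
   "default": -60.0,
   "unit": "mV"
  },
  {
   "name": "g_P",
   "default": 0.0,
   "unit": "nS",
   "min": 0.0
  },
  {
   "name": "E_P",
   "default": 0.0,
   "unit": "mV"
  }
 ],
 "input_slots": [
  "synaptic_current"
 ],
 "aux_functions": {},
 "rhs": {
  "V": "(-(g_L + g_P)*V + I_syn + (g_L*E_L + g_P*E_P))/C"
 },
 "outputs": {
  "V": "V"
 },
 "protected": false
}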