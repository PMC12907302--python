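{
 "name": "cortical_inhibitory",
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
   "name": "V_rest",
   "default": -65.0,
   "unit": "mV"
  },
  {
   "name": "V_thr",
   "default": -50.0,
   "unit": "mV"
  },
  {
   "name": "gain",
   "default": 0.2,
   "unit": "1/mV",
   "min": 0.0
  },
  {
   "name": "nu_max",
   "default": 100.0,
   "unit": "Hz",
   "min": 0.0
  },
  {
   "name": "s_in",
   "default": 1.0,
   "unit": "mV/s/Hz"
  },
  {
   "name": "I_base",
   "default": 0.0,
   "unit": "mV/s"
  }
 ],
 "input_slots": [
  "synaptic_firing_rate"
 ],
 "aux_functions": {},
 "rhs": {
  "V": "-(V - V_rest)/tau + s_in*FR_syn + I_base"
 },
 "outputs": {
  "V": "V",
  "nu": "nu_max*0.5*(1 + erf(gain*(V - V_thr)/sqrt(2)))"
 },
 "protected": true
}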