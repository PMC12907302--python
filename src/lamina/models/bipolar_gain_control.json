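{
 "name": "bipolar_gain_control",
 "kind": "cell",
 "state_vars": [
  {
   "name": "A_B",
   "unit": ""
  },
  {
   "name": "V",
   "unit": "mV"
  }
 ],
 "params": [
  {
   "name": "tau_AB",
   "default": 0.2,
   "unit": "s",
   "min": 1e-06
  },
  {
   "name": "h_B",
   "default": 1.0,
   "unit": "1/(mV s)"
  },
  {
   "name": "theta_B",
   "default": 0.0,
   "unit": "mV"
  },
  {
   "name": "tau_B",
   "default": 0.05,
   "unit": "s",
   "min": 1e-06
  },
  {
   "name": "tau_ext",
   "default": 0.02,
   "unit": "s",
   "min": 1e-06
  },
  {
   "name": "E_L",
   "default": 0.0,
   "unit": "mV"
  }
 ],
 "input_slots": [
  "external",
  "synaptic_voltage_rate"
 ],
 "aux_functions": {
  "N_B": {
   "args": [
    "x"
   ],
   "expr": "max(x - theta_B, 0)"
  }
 },
 "rhs": {
  "A_B": "-A_B/tau_AB + h_B*N_B(V)",
  "V": "-(V - E_L)/tau_B + ext/tau_ext + V_syn"
 },
 "outputs": {
  "V": "V",
  "A_B": "A_B",
  "bipolarResponse": "max(V - theta_B, 0)/(1 + A_B)"
 },
 "protected": false
}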