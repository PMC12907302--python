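{
 "name": "ganglion_gain_control",
 "kind": "cell",
 "state_vars": [
  {
   "name": "V",
   "unit": "mV"
  },
  {
   "name": "A_G",
   "unit": ""
  }
 ],
 "params": [
  {
   "name": "tau_L",
   "default": 0.05,
   "unit": "s",
   "min": 1e-06
  },
  {
   "name": "V_L",
   "default": 0.0,
   "unit": "mV"
  },
  {
   "name": "g_T",
   "default": 0.0,
   "unit": "nS",
   "min": 0.0
  },
  {
   "name": "V_T",
   "default": 0.0,
   "unit": "mV"
  },
  {
   "name": "C",
   "default": 0.1,
   "unit": "nF",
   "min": 1e-09
  },
  {
   "name": "tau_G",
   "default": 0.2,
   "unit": "s",
   "min": 1e-06
  },
  {
   "name": "H_G",
   "default": 1.0,
   "unit": "1/(mV s)"
  },
  {
   "name": "theta_G",
   "default": 0.0,
   "unit": "mV"
  }
 ],
 "input_slots": [
  "synaptic_voltage_rate"
 ],
 "aux_functions": {
  "N_G": {
   "args": [
    "x"
   ],
   "expr": "max(x - theta_G, 0)"
  }
 },
 "rhs": {
  "V": "-(V - V_L)/tau_L + V_syn - (g_T/C)*max(V - V_T, 0)",
  "A_G": "-A_G/tau_G + H_G*N_G(V)"
 },
 "outputs": {
  "V": "V",
  "A_G": "A_G",
  "firingRate": "max(V - theta_G, 0)/(1 + A_G)"
 },
 "protected": false
}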