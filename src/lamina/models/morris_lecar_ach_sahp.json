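{
 "name": "morris_lecar_ach_sahp",
 "kind": "cell",
 "state_vars": [
  {
   "name": "V",
   "unit": "mV"
  },
  {
   "name": "N",
   "unit": ""
  },
  {
   "name": "A",
   "unit": "nM"
  },
  {
   "name": "R",
   "unit": ""
  },
  {
   "name": "S",
   "unit": ""
  }
 ],
 "params": [
  {
   "name": "C",
   "default": 0.02,
   "unit": "nF",
   "min": 1e-09
  },
  {
   "name": "g_Ca",
   "default": 4.4,
   "unit": "nS",
   "min": 0.0
  },
  {
   "name": "g_K",
   "default": 8.0,
   "unit": "nS",
   "min": 0.0
  },
  {
   "name": "g_L",
   "default": 2.0,
   "unit": "nS",
   "min": 0.0
  },
  {
   "name": "V_Ca",
   "default": 120.0,
   "unit": "mV"
  },
  {
   "name": "V_K",
   "default": -84.0,
   "unit": "mV"
  },
  {
   "name": "V_L",
   "default": -60.0,
   "unit": "mV"
  },
  {
   "name": "V1",
   "default": -1.2,
   "unit": "mV"
  },
  {
   "name": "V2",
   "default": 18.0,
   "unit": "mV"
  },
  {
   "name": "V3",
   "default": 2.0,
   "unit": "mV"
  },
  {
   "name": "V4",
   "default": 30.0,
   "unit": "mV"
  },
  {
   "name": "phi",
   "default": 40.0,
   "unit": "Hz",
   "min": 0.0
  },
  {
   "name": "mu_A",
   "default": 50.0,
   "unit": "nM/s",
   "min": 0.0
  },
  {
   "name": "tau_Ach",
   "default": 2.0,
   "unit": "s",
   "min": 1e-06
  },
  {
   "name": "V_Ach",
   "default": -30.0,
   "unit": "mV"
  },
  {
   "name": "kappa_Ach",
   "default": 5.0,
   "unit": "mV"
  },
  {
   "name": "g_sAHP",
   "default": 2.0,
   "unit": "nS",
   "min": 0.0
  },
  {
   "name": "E_K_sAHP",
   "default": -84.0,
   "unit": "mV"
  },
  {
   "name": "tau_R",
   "default": 2.0,
   "unit": "s",
   "min": 1e-06
  },
  {
   "name": "tau_S",
   "default": 2.0,
   "unit": "s",
   "min": 1e-06
  },
  {
   "name": "V_R",
   "default": -25.0,
   "unit": "mV"
  },
  {
   "name": "kappa_R",
   "default": 5.0,
   "unit": "mV"
  }
 ],
 "input_slots": [
  "external",
  "synaptic_current"
 ],
 "aux_functions": {
  "m_inf": {
   "args": [
    "v"
   ],
   "expr": "0.5*(1 + tanh((v - V1)/V2))"
  },
  "n_inf": {
   "args": [
    "v"
   ],
   "expr": "0.5*(1 + tanh((v - V3)/V4))"
  }
 },
 "rhs": {
  "V": "(ext + I_syn - (g_Ca*m_inf(V)*(V - V_Ca) + g_K*N*(V - V_K) + g_L*(V - V_L) + g_sAHP*S^4*(V - E_K_sAHP)))/C",
  "N": "phi*(n_inf(V) - N)*cosh((V - V3)/(2*V4))",
  "A": "-A/tau_Ach + mu_A/(1 + exp(-(V - V_Ach)/kappa_Ach))",
  "R": "(1/(1 + exp(-(V - V_R)/kappa_R)) - R)/tau_R",
  "S": "(R - S)/tau_S"
 },
 "outputs": {
  "V": "V",
  "N": "N",
  "A": "A"
 },
 "protected": false
}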