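{
 "name": "morris_lecar",
 "kind": "cell",
 "state_vars": [
  {
   "name": "V",
   "unit": "mV"
  },
  {
   "name": "N",
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
  "V": "(ext + I_syn - (g_Ca*m_inf(V)*(V - V_Ca) + g_K*N*(V - V_K) + g_L*(V - V_L)))/C",
  "N": "phi*(n_inf(V) - N)*cosh((V - V3)/(2*V4))"
 },
 "outputs": {
  "V": "V",
  "N": "N"
 },
 "protected": false
}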