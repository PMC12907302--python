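{
 "name": "hodgkin_huxley",
 "kind": "cell",
 "state_vars": [
  {
   "name": "V",
   "unit": "mV"
  },
  {
   "name": "m",
   "unit": ""
  },
  {
   "name": "h",
   "unit": ""
  },
  {
   "name": "n",
   "unit": ""
  }
 ],
 "params": [
  {
   "name": "C",
   "default": 0.01,
   "unit": "nF",
   "min": 1e-09
  },
  {
   "name": "g_Na",
   "default": 1200.0,
   "unit": "nS",
   "min": 0.0
  },
  {
   "name": "g_K",
   "default": 360.0,
   "unit": "nS",
   "min": 0.0
  },
  {
   "name": "g_L",
   "default": 3.0,
   "unit": "nS",
   "min": 0.0
  },
  {
   "name": "E_Na",
   "default": 50.0,
   "unit": "mV"
  },
  {
   "name": "E_K",
   "default": -77.0,
   "unit": "mV"
  },
  {
   "name": "E_L",
   "default": -54.387,
   "unit": "mV"
  }
 ],
 "input_slots": [
  "external",
  "synaptic_current"
 ],
 "aux_functions": {
  "a_m": {
   "args": [
    "v"
   ],
   "expr": "1000*0.1*(v + 40)/(1 - exp(-(v + 40)/10))"
  },
  "b_m": {
   "args": [
    "v"
   ],
   "expr": "1000*4*exp(-(v + 65)/18)"
  },
  "a_h": {
   "args": [
    "v"
   ],
   "expr": "1000*0.07*exp(-(v + 65)/20)"
  },
  "b_h": {
   "args": [
    "v"
   ],
   "expr": "1000/(1 + exp(-(v + 35)/10))"
  },
  "a_n": {
   "args": [
    "v"
   ],
   "expr": "1000*0.01*(v + 55)/(1 - exp(-(v + 55)/10))"
  },
  "b_n": {
   "args": [
    "v"
   ],
   "expr": "1000*0.125*exp(-(v + 65)/80)"
  }
 },
 "rhs": {
  "V": "(ext + I_syn - (g_Na*m^3*h*(V - E_Na) + g_K*n^4*(V - E_K) + g_L*(V - E_L)))/C",
  "m": "a_m(V)*(1 - m) - b_m(V)*m",
  "h": "a_h(V)*(1 - h) - b_h(V)*h",
  "n": "a_n(V)*(1 - n) - b_n(V)*n"
 },
 "outputs": {
  "V": "V"
 },
 "protected": false
}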