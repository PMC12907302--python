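{
 "name": "neurotransmitter_amacrine",
 "kind": "cell",
 "state_vars": [
  {
   "name": "T",
   "unit": "nM"
  },
  {
   "name": "V",
   "unit": "mV"
  },
  {
   "name": "n",
   "unit": ""
  }
 ],
 "params": [
  {
   "name": "k_d",
   "default": 5.0,
   "unit": "Hz",
   "min": 0.0
  },
  {
   "name": "k_p",
   "default": 10.0,
   "unit": "nM/s",
   "min": 0.0
  },
  {
   "name": "E_N",
   "default": -40.0,
   "unit": "mV"
  },
  {
   "name": "kappa_N",
   "default": 5.0,
   "unit": "mV"
  },
  {
   "name": "tau_A",
   "default": 0.1,
   "unit": "s",
   "min": 1e-06
  },
  {
   "name": "C_A",
   "default": 0.1,
   "unit": "nF",
   "min": 1e-09
  },
  {
   "name": "beta_n",
   "default": 5.0,
   "unit": "Hz",
   "min": 0.0
  },
  {
   "name": "alpha_n",
   "default": 1.0,
   "unit": "1/(nM s)",
   "min": 0.0
  }
 ],
 "input_slots": [
  "synaptic_current"
 ],
 "aux_functions": {},
 "rhs": {
  "T": "-k_d*T + k_p/(1 + exp(-(V - E_N)/kappa_N))",
  "V": "-V/tau_A + I_syn/C_A",
  "n": "-beta_n*n + alpha_n*T*(1 - n)"
 },
 "outputs": {
  "V": "V",
  "T": "T",
  "n": "n"
 },
 "protected": false
}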