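{
  "name": "parsimonious-rabbit-INa",
  "version": 1,
  "provenance": "Hodgkin-Huxley-type fast sodium current of the parsimonious rabbit ventricular action-potential model (Gray & Pathmanathan, PLoS Comput Biol 2016, Table 1 with erratum). Transcribed values; gate kinetics: m_inf(V)=1/(1+exp(-(V-E_m)/k_m)), constant tau_m; h_inf(V)=1/(1+exp((V-E_h)/k_h)), tau_h(V)=2*tau_h0*exp(delta_h*(V-E_h)/k_h)/(1+exp((V-E_h)/k_h)). I_Na = g_Na * m^3 * h * (V - E_Na), so the current is inward (negative) below the sodium reversal potential.",
  "units": {
    "g_Na": "mS/cm^2 (= uA cm^-2 mV^-1)",
    "E_Na": "mV",
    "E_m": "mV",
    "k_m": "mV",
    "tau_m": "ms",
    "E_h": "mV",
    "k_h": "mV",
    "tau_h0": "ms",
    "delta_h": "dimensionless"
  },
  "parameters": {
    "g_Na": 11.0,
    "E_Na": 65.0,
    "E_m": -41.0,
    "k_m": 4.0,
    "tau_m": 0.12,
    "E_h": -74.9,
    "k_h": 4.4,
    "tau_h0": 6.80738,
    "delta_h": 0.799163,
    "m_exponent": 3,
    "h_exponent": 1
  }
}
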