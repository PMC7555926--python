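# Baseline node/internode axon parameter set (version 1).
# The absolute scale (capacitances, conductances, pump current together)
# sets how much a given pA-scale current perturbation matters; it is chosen
# for a small rat motor axon (1-ms threshold ~40 pA at the node), leaving
# every percentage-based excitability index unchanged.
# Units: capacitance pF, conductance nS, current pA, potential mV, time ms.
# Free calibration inputs for a rat motor axon: the working baseline is
# obtained by fitting the control-group excitability indices
# (axotrace.fitting.calibrate_baseline); these defaults are that fit's
# starting point, not a claim about any particular animal.
C_n: 0.125              # nodal capacitance, pF
C_i: 14.623011833333333    # internodal capacitance, pF
G_BB: 1.157509  # Barrett-Barrett coupling conductance, nS
G_Lk_n: 0.15034308333333332   # nodal leak, nS
G_Lk_i: 1.6365266666666667   # internodal leak, nS
G_NaT: 32.223822166666665     # maximal nodal transient Na+ conductance, nS
f_NaP: 0.002117     # persistent fraction of Na+ conductance
G_Ks_n: 1.9819169999999997   # slow K+ at node, nS
G_Ks_i: 0.16666666666666666   # slow K+ at internode, nS
G_Kf_n: 2.3739614166666665   # fast K+ at node, nS
G_Kf_i: 1.935196   # fast K+ at internode (juxtaparanodal), nS
G_H: 3.1492845000000003         # internodal HCN conductance, nS
E_Na: 55.0
E_K: -95.154838         # [K]o ~3-4 mM at 37 C
E_H: -50.0
E_Lk: -84.0
I_pump: 2.1182789166666662   # net outward Na+/K+-pump current, pA
f_pump_node: 0.0075   # nodal share of pump current (~ capacitance ratio)
T: 37.0
T_ref: 37.0
q10:
  m: 2.2
  h: 2.9
  p: 2.2
  s: 3.0
  nf: 3.0
  q: 3.0
# Voltage-gated kinetics.  m and p use mirrored exponential pairs
# (alpha = A*exp((V-B)/C), beta the mirror image): steady state
# 1/(1+exp(-2(V-B)/C)), peak time constant 1/(2A) at V = B.  h uses a
# saturating sigmoid pair with independent forward/backward ceilings so
# inactivation stays finite-rate at spike voltages (robustly overshooting
# action potentials).  s, nf and q use complementary sigmoid pairs
# (voltage-independent time constant 1/A).
rate_coeffs:
  m:
    alpha: {form: expg, A: 8.877493, B: -40.914715, C: 10.0}
    beta: {form: expg, A: 8.877493, B: -40.914715, C: -10.0}
  h:
    alpha: {form: sigmoid, A: 0.656662, B: -61.220731, C: -5.31641}
    beta: {form: sigmoid, A: 1.974677, B: -61.220731, C: 5.31641}
  p:
    alpha: {form: expg, A: 0.4, B: -48.26798, C: 10.0}
    beta: {form: expg, A: 0.4, B: -48.26798, C: -10.0}
  s:
    alpha: {form: sigmoid, A: 0.055082, B: -46.895201, C: 11.456944}
    beta: {form: sigmoid, A: 0.055082, B: -46.895201, C: -11.456944}
  nf:
    alpha: {form: sigmoid, A: 0.344781, B: -45.356441, C: 9.0}
    beta: {form: sigmoid, A: 0.344781, B: -45.356441, C: -9.0}
  q:
    alpha: {form: sigmoid, A: 0.01, B: -96.056564, C: -7.0}
    beta: {form: sigmoid, A: 0.01, B: -96.056564, C: 7.0}
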