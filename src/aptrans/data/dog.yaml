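# Dog ventricular parameterization.
# Units: conductances mS/uF; g_CaL nL/(uF*ms); Ibar_* uA/uF;
# concentrations mM as [intracellular, extracellular]; temperature K;
# stim_amplitude A/F (1.5x the diastolic threshold, frozen at build time).
species_name: dog
g_Kr: 0.016
g_CaL: 0.077
g_Na: 1.4
g_Ks: 0.1
g_KL: 0.52
g_to: 0.31
g_NaL: 0.0042
Ibar_NaCa: 5.9
Ibar_NaK: 1.4
g_bCl: 0.00013
g_bCa: 0.00065
Ibar_pCa: 0.58
g_CaT: 0.0
ion_concentrations:
  Na: [10.0, 140.0]
  K: [145.0, 5.4]
  Ca: [0.0001, 1.8]
  Cl: [24.0, 150.0]
temperature: 310.0
stim_amplitude: 16.5
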