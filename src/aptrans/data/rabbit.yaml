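# Rabbit ventricular parameterization.
# Units: conductances mS/uF; g_CaL nL/(uF*ms); Ibar_* uA/uF;
# concentrations mM as [intracellular, extracellular]; temperature K;
# stim_amplitude A/F (1.5x the diastolic threshold, frozen at build time).
species_name: rabbit
g_Kr: 0.087
g_CaL: 0.25
g_Na: 2.3
g_Ks: 0.016
g_KL: 0.35
g_to: 0.17
g_NaL: 0.027
Ibar_NaCa: 9.8
Ibar_NaK: 2.8
g_bCl: 0.011
g_bCa: 0.0005
Ibar_pCa: 0.064
g_CaT: 0.0
ion_concentrations:
  Na: [10.0, 140.0]
  K: [120.0, 5.4]
  Ca: [0.0001, 1.8]
  Cl: [24.0, 150.0]
temperature: 310.0
stim_amplitude: 13.0
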