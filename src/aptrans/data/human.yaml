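# Human ventricular parameterization.
# Units: conductances mS/uF; g_CaL nL/(uF*ms); Ibar_* uA/uF;
# concentrations mM as [intracellular, extracellular]; temperature K;
# stim_amplitude A/F (1.5x the diastolic threshold, frozen at build time).
species_name: human
g_Kr: 0.033
g_CaL: 0.17
g_Na: 5.0
g_Ks: 0.003
g_KL: 0.074
g_to: 0.54
g_NaL: 0.025
Ibar_NaCa: 4.9
Ibar_NaK: 1.8
g_bCl: 0.0056
g_bCa: 0.00055
Ibar_pCa: 0.068
g_CaT: 0.0
ion_concentrations:
  Na: [10.0, 140.0]
  K: [120.0, 5.4]
  Ca: [0.0001, 1.8]
  Cl: [24.0, 150.0]
temperature: 310.0
stim_amplitude: 10.7
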