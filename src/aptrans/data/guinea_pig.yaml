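# Guinea pig ventricular parameterization.
# Units: conductances mS/uF; g_CaL nL/(uF*ms); Ibar_* uA/uF;
# concentrations mM as [intracellular, extracellular]; temperature K;
# stim_amplitude A/F (1.5x the diastolic threshold, frozen at build time).
species_name: guinea_pig
g_Kr: 0.06
g_CaL: 0.21
g_Na: 0.9
g_Ks: 0.69
g_KL: 0.85
g_to: 0.0
g_NaL: 0.03
Ibar_NaCa: 15.86
Ibar_NaK: 1.62
g_bCl: 0.0
g_bCa: 0.0
Ibar_pCa: 0.6
g_CaT: 0.0
ion_concentrations:
  Na: [10.0, 140.0]
  K: [120.0, 5.4]
  Ca: [0.0001, 1.8]
  Cl: [24.0, 150.0]
temperature: 310.0
stim_amplitude: 15.3
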