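# Zebrafish ventricular parameterization.
# Units: conductances mS/uF; g_CaL nL/(uF*ms); Ibar_* uA/uF;
# concentrations mM as [intracellular, extracellular]; temperature K;
# stim_amplitude A/F (1.5x the diastolic threshold, frozen at build time).
species_name: zebrafish
g_Kr: 0.044
g_CaL: 0.086
g_Na: 2.2
g_Ks: 0.0024
g_KL: 0.86
g_to: 0.0035
g_NaL: 0.028
Ibar_NaCa: 4.2
Ibar_NaK: 9.2
g_bCl: 0.00087
g_bCa: 0.0019
Ibar_pCa: 0.056
g_CaT: 0.056
ion_concentrations:
  Na: [10.0, 140.0]
  K: [120.0, 5.4]
  Ca: [0.0001, 1.8]
  Cl: [24.0, 150.0]
temperature: 310.0
stim_amplitude: 17.7
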