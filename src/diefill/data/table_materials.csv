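name,x10_um,x50_um,x90_um,rho_bulk_g_cm3,rho_tapped_g_cm3,rho_particle_g_cm3,permeability_m2
DCP,70.2,167.0,292.3,0.738,0.870,2.838,5.20e-12
MCC,34.1,127.0,263.3,0.355,0.455,1.595,4.62e-12
LAC,5.3,33.7,118.5,0.528,0.784,1.548,5.61e-13
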