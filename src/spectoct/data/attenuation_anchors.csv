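# Standard tabulated mass attenuation coefficients near 12.66 keV,
# rounded to two significant figures.  Elemental Se values bracket its
# K edge (12.658 keV); matrix materials are smooth across the range.
material,energy_keV,mu_rho_cm2_g,note
Se,12.645,7.0,elemental Se just below its K edge
Se,12.685,46.0,elemental Se just above its K edge
PMMA,12.660,1.70,acrylic matrix; smooth across the range
BN,12.660,1.50,boron nitride powder diluent; smooth across the range
cellulose,12.660,1.90,tissue paper cap; smooth across the range
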