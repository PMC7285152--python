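# Mass interaction coefficients for sodium iodide (NaI), cm^2/g, by process:
# photoelectric absorption (tau), incoherent (Compton) scattering (sigma_inc),
# and pair production, nuclear + electron field (kappa).
# Approximate values: smooth log-log representation of the NIST XCOM photon
# cross section database for NaI, adequate for the simplified single-scatter
# transport model in this package (coherent scattering omitted; it removes no
# energy from the beam at these energies in a 2x2 inch crystal).
# Valid range 40-4000 keV (above the iodine K edge at 33.2 keV).
# Columns: energy_keV, tau_photo_cm2_g, sigma_incoherent_cm2_g, kappa_pair_cm2_g
40,20.8,0.154,0.0
50,10.6,0.149,0.0
60,6.20,0.144,0.0
80,2.60,0.134,0.0
100,1.33,0.127,0.0
150,0.394,0.114,0.0
200,0.166,0.104,0.0
300,0.0512,0.0889,0.0
400,0.0223,0.0814,0.0
500,0.0119,0.0743,0.0
600,0.00716,0.0690,0.0
800,0.00340,0.0604,0.0
1000,0.00198,0.0543,0.0
1250,0.00123,0.0486,0.00003
1500,0.00085,0.0456,0.00035
2000,0.00051,0.0398,0.0013
2500,0.00035,0.0358,0.0023
3000,0.00026,0.0324,0.0032
4000,0.00017,0.0278,0.0048
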