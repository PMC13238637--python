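# NIST (Hubbell & Seltzer) photon mass attenuation coefficients, 10-150 keV.
# mu_over_rho and muen_over_rho in cm^2/g; muen tabulated only where the package needs it (air).
# Tungsten carries a two-sided point at the K edge (69.525 keV); its L edges (10.2-12.1 keV)
# are not resolved because every supported beam is filtered well past them.
material,energy_keV,mu_over_rho,muen_over_rho
hydrogen,10,0.3854,
hydrogen,15,0.3764,
hydrogen,20,0.3695,
hydrogen,30,0.3570,
hydrogen,40,0.3458,
hydrogen,50,0.3355,
hydrogen,60,0.3260,
hydrogen,80,0.3091,
hydrogen,100,0.2944,
hydrogen,150,0.2651,
carbon,10,2.373,
carbon,15,0.8071,
carbon,20,0.4420,
carbon,30,0.2562,
carbon,40,0.2076,
carbon,50,0.1871,
carbon,60,0.1753,
carbon,80,0.1610,
carbon,100,0.1514,
carbon,150,0.1347,
oxygen,10,5.952,
oxygen,15,1.836,
oxygen,20,0.8651,
oxygen,30,0.3779,
oxygen,40,0.2585,
oxygen,50,0.2132,
oxygen,60,0.1907,
oxygen,80,0.1678,
oxygen,100,0.1551,
oxygen,150,0.1361,
aluminium,10,26.23,
aluminium,15,7.955,
aluminium,20,3.441,
aluminium,30,1.128,
aluminium,40,0.5685,
aluminium,50,0.3681,
aluminium,60,0.2778,
aluminium,80,0.2018,
aluminium,100,0.1704,
aluminium,150,0.1378,
copper,10,215.9,
copper,15,74.05,
copper,20,33.79,
copper,30,10.92,
copper,40,4.862,
copper,50,2.613,
copper,60,1.593,
copper,80,0.7630,
copper,100,0.4584,
copper,150,0.2217,
tungsten,10,96.91,
tungsten,15,139.3,
tungsten,20,65.73,
tungsten,30,22.73,
tungsten,40,10.67,
tungsten,50,5.949,
tungsten,60,3.713,
tungsten,69.52,2.552,
tungsten,69.53,11.23,
tungsten,80,7.810,
tungsten,100,4.438,
tungsten,150,1.581,
air,10,5.120,4.742
air,15,1.614,1.334
air,20,0.7779,0.5389
air,30,0.3538,0.1537
air,40,0.2485,0.06833
air,50,0.2080,0.04098
air,60,0.1875,0.03041
air,80,0.1662,0.02407
air,100,0.1541,0.02325
air,150,0.1356,0.02496
pmma,10,3.357,
pmma,15,1.101,
pmma,20,0.5714,
pmma,30,0.3032,
pmma,40,0.2350,
pmma,50,0.2074,
pmma,60,0.1924,
pmma,80,0.1751,
pmma,100,0.1641,
pmma,150,0.1456,
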