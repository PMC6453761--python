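# Mass attenuation coefficient of elemental iodine (Z=53), NIST grid
# with extra points bracketing the K edge at 33.17 keV.
# energy_kev,mass_attenuation_cm2_g
10,162.0
15,54.0
20,25.6
30,8.561
33.0,6.64
33.2,35.8
40,22.1
50,12.32
60,7.579
80,3.510
100,1.942
150,0.710
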