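complex,cation,site,e_cation_pi,e_pi_pi,e_water_pi,e_water_water,e_water_cation,e_sum,e_binding
Li+@3Bz,Li,gas,-0.54,-2.08,0.00,0.00,0.00,-2.63,-2.63
Li+2W@3Bz,Li,coordinated,-0.54,-2.08,0.57,0.06,-3.11,-5.10,-1.31
Li+@3Bz-3W,Li,hollow,-0.54,-2.08,0.48,0.25,-2.17,-4.07,-4.93
Li+@3Bz-6W,Li,bridge,-0.54,-2.08,-6.80,1.84,-6.26,-13.84,-12.06
Li+2W@3Bz-9W,Li,total,-0.54,-2.08,-7.53,7.49,-9.33,-12.00,-8.31
Na+@3Bz,Na,gas,-12.12,-5.41,0.00,0.00,0.00,-17.53,-17.53
Na+2W@3Bz,Na,coordinated,-12.12,-5.41,2.97,0.26,-6.82,-21.11,-11.18
Na+@3Bz-3W,Na,hollow,-12.12,-5.41,-1.76,0.25,-3.68,-22.72,-20.84
Na+@3Bz-6W,Na,bridge,-12.12,-5.41,-8.46,1.93,-8.37,-32.43,-28.21
Na+2W@3Bz-9W,Na,total,-12.12,-5.41,-4.26,1.48,-18.18,-38.50,-26.44
K+@3Bz,K,gas,-12.17,-6.62,0.00,0.00,0.00,-18.78,-18.78
K+2W@3Bz,K,coordinated,-12.17,-6.62,0.32,-0.13,1.13,-17.47,-15.24
K+@3Bz-3W,K,hollow,-12.17,-6.62,-0.15,0.25,-4.47,-23.16,-23.03
K+@3Bz-6W,K,bridge,-12.17,-6.62,-6.71,1.88,-9.34,-32.95,-30.93
K+2W@3Bz-9W,K,total,-12.17,-6.62,-6.73,3.67,-11.84,-33.68,-29.06
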