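system,cation,e_elst,e_exch,e_ind,e_disp,e_tot
gas,Li,-70.49,109.10,-39.22,-59.63,-60.24
gas,Na,-58.62,72.76,-30.32,-44.88,-61.07
gas,K,-47.40,46.21,-24.95,-35.82,-61.96
coordinated,Li,-65.03,112.67,-32.56,-65.26,-50.18
coordinated,Na,-56.10,102.77,-21.78,-58.78,-33.88
coordinated,K,-40.76,61.45,-17.17,-45.40,-41.89
hollow,Li,-88.27,114.20,-37.59,-61.48,-73.14
hollow,Na,-75.86,76.34,-28.94,-46.38,-74.84
hollow,K,-63.36,48.39,-24.07,-37.05,-76.09
bridge,Li,-94.87,111.56,-36.37,-63.36,-83.03
bridge,Na,-82.90,74.62,-27.93,-47.94,-84.15
bridge,K,-70.52,47.22,-23.06,-38.09,-84.45
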