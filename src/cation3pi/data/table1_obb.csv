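cation,gas,coordinated,hollow,bridge,total,gas_ref
Li,-2.63,-1.31,-4.93,-12.06,-8.31,1.31
Na,-17.53,-11.18,-20.84,-28.21,-26.44,-12.08
K,-18.78,-15.24,-23.03,-30.93,-29.06,-14.60
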