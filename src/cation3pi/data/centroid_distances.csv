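cation,n_benzene,d_centroid
Li,2,1.9
Li,3,2.5
Na,2,2.4
Na,3,2.6
K,2,3.0
K,3,2.9
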