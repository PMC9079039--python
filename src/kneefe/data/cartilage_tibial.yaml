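# FRPVE parameters, tibial cartilage.
E_m: 0.106
E_0: 0.18
E_eps: 23.06
nu_m: 0.15
eta: 1062.0
k_0: 18.0
n_f_surface: 0.8
n_f_slope: 0.15
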