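# FRPVE parameters, femoral cartilage. Moduli MPa, eta MPa*s,
# k_0 in 1e-15 m^4/(N s); n_f(h_z) = n_f_surface - n_f_slope * h_z.
E_m: 0.215
E_0: 0.92
E_eps: 150.0
nu_m: 0.15
eta: 1062.0
k_0: 6.0
n_f_surface: 0.8
n_f_slope: 0.15
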