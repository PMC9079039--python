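# Transversely isotropic meniscus; axis 3 = circumferential. Moduli MPa.
E_1: 20.0
E_2: 20.0
E_3: 159.6
nu_12: 0.3
nu_31: 0.78
G_13: 50.0
n_f: 0.72
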