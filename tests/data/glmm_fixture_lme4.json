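{"coefficients": {"(Intercept)": -1.3746212888, "x1": 0.7374806124, "x2": -0.5031404622},
 "se": {"(Intercept)": 0.1222307944, "x1": 0.1095608769, "x2": 0.0452055382},
 "random_sd": {"farm": 0.5697766116, "semester": 0.1759791287},
 "loglik": -516.2052551856}
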