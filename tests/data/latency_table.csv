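participant,mu_erd_left_car,mu_erd_left_bip,mu_erd_right_car,mu_erd_right_bip,beta_erd_left_car,beta_erd_left_bip,beta_erd_right_car,beta_erd_right_bip,beta_ers_left_car,beta_ers_left_bip,beta_ers_right_car,beta_ers_right_bip
P1,2.62,2.75,2.80,2.90,1.90,1.80,1.82,2.00,4.20,4.65,4.50,4.50
P2,2.83,2.32,2.73,1.90,2.11,2.25,1.95,2.10,3.85,3.95,4.05,3.90
P3,1.80,2.10,2.22,2.10,1.62,2.15,1.78,1.95,2.80,2.75,3.15,3.05
P4,2.64,2.60,2.75,3.00,2.23,1.75,2.15,1.90,3.80,2.75,3.65,3.58
P5,2.70,2.65,2.42,2.55,1.75,1.88,2.17,1.65,2.65,2.88,2.60,2.58
P6,1.71,1.85,1.90,2.10,1.90,2.00,1.78,1.85,2.89,3.05,2.79,2.85
P7,2.00,2.10,2.15,2.60,1.81,1.74,1.77,1.75,3.52,3.65,3.55,3.80
P8,2.31,2.20,2.62,2.52,1.94,2.10,1.65,1.60,3.35,3.30,3.30,3.55
P9,2.45,2.15,2.20,2.52,1.60,1.70,2.15,2.25,3.55,3.78,3.60,3.58
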