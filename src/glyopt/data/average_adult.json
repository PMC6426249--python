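{
 "basal_glucose": 130.0,
 "basal_state": {
  "Gp": 244.39999999999998,
  "Gt": 186.75598466537636,
  "H": 93.12567203815448,
  "Hsc1": 0.0,
  "Hsc2": 0.0,
  "I1": 0.0,
  "Il": 0.0,
  "Ip": 0.0,
  "Isc1": 0.0,
  "Isc2": 0.0,
  "Qgut": 0.0,
  "Qsto1": 0.0,
  "Qsto2": 0.0,
  "SRHs": 18.600134407630893,
  "X": 0.0,
  "XH": 0.3206118233984061,
  "XL": 0.0
 },
 "values": {
  "BW": 78.0,
  "Fcns": 1.0,
  "Gth": 130.0,
  "Hb": 93.0,
  "Ib": 0.0,
  "Km0": 225.59,
  "SRHb": 18.6,
  "U_to_pmol": 6000.0,
  "VG": 1.88,
  "VH": 0.25,
  "VI": 0.05,
  "Vm0": 2.5,
  "Vmx": 0.034119193225488294,
  "b": 0.82,
  "c": 0.00236,
  "delta": 0.682,
  "f": 0.9,
  "k1": 0.065,
  "k2": 0.079,
  "kH": 0.16,
  "ka1": 0.0018,
  "ka2": 0.03,
  "kabs": 0.057,
  "kd": 0.03,
  "ke1": 0.0005,
  "ke2": 339.0,
  "kgri": 0.0558,
  "kh1": 0.15,
  "kh2": 0.005,
  "kh3": 0.12,
  "ki": 0.011,
  "kmax": 0.0558,
  "kmin": 0.008,
  "kp1": 2.6451861963809624,
  "kp2": 0.0021,
  "kp3": 0.009,
  "m1": 0.19,
  "m2": 0.484,
  "m3": 0.285,
  "m4": 0.194,
  "mg_to_ng": 1000000.0,
  "n": 0.2,
  "p2U": 0.0331,
  "rho": 0.86,
  "sigma": 1.093,
  "w_egp": 0.01,
  "w_renal": 1.0,
  "w_srhd": 0.05,
  "w_srhs": 0.1,
  "w_xh": 0.5,
  "xi": 0.001
 }
}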