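# Population PK parameter fixture: fixed effects, interindividual (IIV) and
# interoccasion (IOV) variability as %CV of the log-normal random effects, and
# residual-error components per observation stream.
#
# Units: clearances L/h, volumes L, rates 1/h, ksyn nM/h, Ki uM, MTT h.
# Residual errors: sigma_prop dimensionless fraction; sigma_add in the units
# of the observation stream (RIF plasma uM; CPI plasma nM; CPI urine nmol;
# RSV plasma uM; RSV urine nmol).
version: "1.0"
constants:
  fu_rif: 0.11
  rif_mw_g_mol: 822.94
  rsv_mw_g_mol: 481.54
rifampicin:
  dose_mg: 600.0
  fixed:
    ka: 2.09       # 1/h
    CL: 3.97       # L/h
    V: 24.7        # L
    MTT: 0.74      # h
    n: 8.63        # transit compartments (continuous)
  iiv_cv: {ka: 46.0, CL: 30.7, V: 19.5, MTT: 69.1, n: 24.3}
  iov_cv: {ka: 49.2, V: 6.6, MTT: 47.6}
  error:
    rif_plasma: {sigma_prop: 0.313, sigma_add: 0.01}   # add in uM
cpi:
  fixed:
    ksyn: 12.7     # nM/h
    CLb: 12.3      # L/h
    CLR: 1.64      # L/h
    V: 6.59        # L
    V_rif: 3.4     # L, volume under perpetrator co-administration
    Ki: 1.15       # uM, total (unbound = Ki * fu_rif)
  iiv_cv: {ksyn: 2.9, CLb: 14.3, CLR: 9.5, V: 35.2, Ki: 18.8}
  iov_cv: {ksyn: 5.5, CLb: 18.3}
  error:
    cpi_plasma: {sigma_prop: 0.139, sigma_add: 0.001}  # add in nM
    cpi_urine: {sigma_prop: 0.342, sigma_add: 2.69}    # add in nmol
rosuvastatin:
  dose_mg: 5.0
  fixed:
    ka: 0.287      # 1/h
    CLR: 8.48      # L/h
    CLb: 124.0     # L/h
    V1: 430.0      # L
    V2: 865.0      # L
    Q: 45.3        # L/h
    V1_rif: 2.98   # L
    V2_rif: 128.0  # L
    Q_rif: 5.03    # L/h
    Ki: 2.23       # uM, total
  iiv_cv: {ka: 15.4, CLR: 37.9, CLb: 34.4, V1: 21.8, Q: 45.2, Ki: 33.4}
  iov_cv: {ka: 17.7}
  error:
    rsv_plasma: {sigma_prop: 0.257, sigma_add: 5.0e-05}  # add 0.05 nM in uM
    rsv_urine: {sigma_prop: 0.578, sigma_add: 0.1}       # add in nmol
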