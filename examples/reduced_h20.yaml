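# Reduced-scale study: two-rung dynamin (H = 20 nm) on a 16.6 nm tubule.
# Domain 30 x 360 nm at the production spacing (dr = dz ~ 0.28 nm ~ eps/3).
grid:
  L_r_nm: 30.0
  L_z_nm: 360.0
  N_r: 108
  N_z: 1296
gamma_N_per_m: 1.5e-4          # reservoir tension -> R_in = 16.6 nm
elastic:
  k_b: 20.0                    # k_BT
  k_G: -20.0                   # k_BT (Gaussian modulus, ~ -k_b)
  M_pf: 4.04                   # nm^3/(s kBT)
coats:
  - H_nm: 20.0
    center_nm: 180.0
    F_tau_pN: 2.5
    pitch_nm: 10.0
    N_d: 13
    R_cut_nm: 3.0
stepper:
  record_every: 10
  dphi_target: 0.01            # per-step interface accuracy
post_fission_time: 0.2         # s of unforced relaxation after severing
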