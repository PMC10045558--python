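# Example in vivo beam configuration (heavy-water facility, 5 MW run).
#
# All entries are calibration inputs for a particular facility and
# geometry, not physical constants.  kerma.B10 is the standard thermal
# capture value per ug 10B/g; kerma.N14/H1 and the gamma dose rate are
# set so that a boron-free 20 min exposure reproduces the beam-only
# reference decomposition (0.5 Gy N+H, 1.1 Gy gamma).
beam:
  thermal_flux: 9.6e+8          # n cm^-2 s^-1
  gamma_dose_rate: 9.1667e-4    # Gy/s  (1.1 Gy over 1200 s)
  kerma:
    B10: 8.66e-14               # Gy cm^2 per (ug 10B/g)
    N14: 2.17e-13               # Gy cm^2 (reference tissue N content)
    H1: 2.17e-13                # Gy cm^2 (recoil; thermal-driven here)
factors:
  rbe_n: 3.0
  rbe_h: 3.0
  cbe:
    BPA:
      tumor: 2.69
      brain: 1.35
    cRGD-MID-AC:
      tumor: 2.26
      # brain: unknown -> photon-equivalent cells stay blank
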