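# In vivo dose-table scenario: published physical and photon-equivalent
# doses (Gy / Gy-Eq) for brain and tumor per treatment group, plus the
# factor set used to weight them.  The boron-free "neutron only" row
# doubles as the beam calibration input: its (physical, photon-equivalent)
# pair determines the lumped N+H and gamma components given RBE_NH.
rbe_nh: 3.0
cbe:
  BPA:
    tumor: 2.69
    brain: 1.35
  cRGD-MID-AC:
    tumor: 2.26
    # brain CBE unknown: report cells stay blank
beam_only_row: {physical: 1.6, photon_equivalent: 2.6}
rows:
  - {group: "Untreated",                     carrier: null,          physical_brain: 0.0, physical_tumor: 0.0, eq_brain: 0.0, eq_tumor: 0.0}
  - {group: "Neutron only",                  carrier: null,          physical_brain: 1.6, physical_tumor: 1.6, eq_brain: 2.6, eq_tumor: 2.6}
  - {group: "BNCT using BPA 2.5 h",          carrier: BPA,           physical_brain: 2.2, physical_tumor: 4.6, eq_brain: 3.4, eq_tumor: 10.9}
  - {group: "BNCT using BPA 8 h",            carrier: BPA,           physical_brain: 2.2, physical_tumor: 4.2, eq_brain: 3.3, eq_tumor: 9.9}
  - {group: "BNCT using cRGD-MID-AC 2.5 h",  carrier: cRGD-MID-AC,   physical_brain: 1.5, physical_tumor: 2.9, eq_brain: null, eq_tumor: 5.8}
  - {group: "BNCT using cRGD-MID-AC 8 h",    carrier: cRGD-MID-AC,   physical_brain: 1.8, physical_tumor: 4.6, eq_brain: null, eq_tumor: 9.5}
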