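# In vivo survival scenario: six groups of F98 glioma-bearing rats
# observed after neutron irradiation.  mean/sd/median are the published
# group summaries (days after implantation).  Simulated times are
# log-normal, anchored to the group median with scale set by the
# mean/SD coefficient of variation; the censoring horizon encodes the
# study end (one long-term survivor censored at 90 days).
censor_horizon_days: 90
reference_group: untreated
groups:
  - {name: untreated,                  n: 5, mean: 30.0, sd: 4.0,  median: 30.0}
  - {name: neutron only,               n: 4, mean: 33.0, sd: 7.7,  median: 35.0}
  - {name: BNCT using BPA 2.5 h,       n: 6, mean: 43.0, sd: 3.8,  median: 42.0}
  - {name: BNCT using BPA 8 h,         n: 5, mean: 40.2, sd: 5.6,  median: 40.0}
  - {name: BNCT using cRGD-MID-AC 2.5 h, n: 7, mean: 42.4, sd: 8.6, median: 43.0}
  - {name: BNCT using cRGD-MID-AC 8 h, n: 6, mean: 50.3, sd: 26.8, median: 38.5}
# Published %ILS values (vs untreated median 30.0) for cross-checks.
published_pct_ils:
  neutron only: 16.7
  BNCT using BPA 2.5 h: 40.0
  BNCT using BPA 8 h: 33.3
  BNCT using cRGD-MID-AC 2.5 h: 43.3
  BNCT using cRGD-MID-AC 8 h: 28.3
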