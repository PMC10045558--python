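# Tissue boron biodistribution scenario: F98 glioma-bearing rats,
# 12 mg B/kg i.v., tissues sampled at 2.5/8/24 h.  Means and SDs
# (ug B/g) are the published group summaries; n is animals per cell.
# Replicates are drawn from a normal truncated at zero.
tissues: [tumor, brain, blood]
cells:
  - {carrier: cRGD-MID-AC, time_h: 2.5, n: 4, tumor: [10.1, 1.6], brain: [0.8, 0.2], blood: [41.6, 5.6]}
  - {carrier: cRGD-MID-AC, time_h: 8,   n: 4, tumor: [17.0, 1.8], brain: [0.9, 0.1], blood: [40.3, 8.4]}
  - {carrier: cRGD-MID-AC, time_h: 24,  n: 4, tumor: [13.1, 1.9], brain: [0.7, 0.1], blood: [17.7, 2.3]}
  - {carrier: BPA, time_h: 2.5, n: 4, tumor: [20.6, 2.2], brain: [5.5, 0.6], blood: [7.7, 0.5]}
  - {carrier: BPA, time_h: 8,   n: 3, tumor: [18.2, 2.9], brain: [5.3, 0.5], blood: [4.8, 0.3]}
  - {carrier: BPA, time_h: 24,  n: 4, tumor: [8.2, 0.8],  brain: [2.3, 0.3], blood: [2.9, 0.4]}
# Published display ratios (tumor/brain, tumor/blood) for cross-checks.
published_ratios:
  - {carrier: cRGD-MID-AC, time_h: 2.5, t_br: 12.5, t_bl: 0.2}
  - {carrier: cRGD-MID-AC, time_h: 8,   t_br: 18.5, t_bl: 0.4}
  - {carrier: cRGD-MID-AC, time_h: 24,  t_br: 18.4, t_bl: 0.7}
  - {carrier: BPA, time_h: 2.5, t_br: 3.8, t_bl: 2.7}
  - {carrier: BPA, time_h: 8,   t_br: 3.4, t_bl: 3.8}
  - {carrier: BPA, time_h: 24,  t_br: 3.6, t_bl: 2.8}
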