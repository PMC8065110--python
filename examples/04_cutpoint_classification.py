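"""Occupancy classification: ROC, Index-of-Union cut-point, envelopes.

Fits the habitat model, chooses the cut-point c minimising
IU(c) = |Se(c) - AUC| + |Sp(c) - AUC|, and reports the core-habitat
envelope (covariate region with predicted probability >= c).
"""

import bathytherm as bt

scen = bt.default_scenario(seed=2)
occ = bt.simulate_occupancy(scen.truth, scen.grid, scen.climatology, seed=3)
fit = bt.fit_logistic(occ)

scores = bt.predict_probability(fit, occ.sst_c.to_numpy(), occ.depth_m.to_numpy())
roc = bt.roc_curve(scores, occ.y.to_numpy())
cut = bt.iu_cutpoint(roc)
print(f"AUC                : {roc.auc:.3f}")
print(f"IU-optimal c       : {cut.c:.3f}  (Se={cut.se_at_c:.2f}, Sp={cut.sp_at_c:.2f},"
      f" IU={cut.iu_value:.3f})")

env = bt.core_habitat_envelope(fit, cut.c)
print(f"core habitat       : SST {env.sst_interval[0]:.1f}-{env.sst_interval[1]:.1f} degC, "
      f"depth {env.depth_interval[0]:.0f}-{env.depth_interval[1]:.0f} m")
print()
print("Cells with predicted presence probability at or above c form the")
print("core habitat; the envelope is its bounding box in covariate space.")
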