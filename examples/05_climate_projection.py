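"""End-to-end pipeline: delta-method projection of occupancy under warming.

Runs every stage on the default synthetic study system (3 degC mean
warming over 80 years, north warming about twice as fast as the south)
and prints the occupied-fraction trend by season and decade.
"""

import bathytherm as bt

res = bt.run_pipeline(bt.PipelineConfig(seed=1))
print(f"fitted optimum : {res.fit.peak_sst:.2f} degC / {res.fit.peak_depth:.1f} m "
      f"(planted 21.5 / 50)")
print(f"AUC={res.roc.auc:.3f}  c={res.cutpoint.c:.3f}")
print()
print("occupied fraction of shelf cells (bin 0 = observed era, then decades):")
wide = res.trend.pivot(index="bin", columns="season", values="occupied_fraction")
print(wide[["winter", "spring", "summer", "fall"]].round(3).to_string())
print()
final = res.trend[res.trend.bin == res.trend.bin.max()].set_index("season")
print("change vs observed era by the final decade:")
for s in ("winter", "spring", "summer", "fall"):
    print(f"  {s:7s}: {final.loc[s, 'change_vs_observed']:+.3f}")
print()
print("Warming expands suitable habitat northward in spring and fall,")
print("changes winter minimally (the shelf stays too cold), and slightly")
print("erodes summer habitat where SST passes the thermal optimum.")
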