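"""Closed-loop comparison of the two controllers on a simulated soil bed.

The default bed mirrors the hardware trial: two valve zones, one loaded
with dried soil and one saturated.  Both controllers face identical initial
states and noise streams for each seed.
"""

from agriflow.soilbed_sim import SoilBedConfig, compare_controllers

report = compare_controllers(SoilBedConfig(), duration_s=3600.0, seeds=range(5))
df = report["per_seed"]
print(df.round(1).to_string(index=False))
print(f"\nfuzzy dispensed less water in {report['fuzzy_wins_volume']}/"
      f"{report['n_seeds']} runs and was open less in "
      f"{report['fuzzy_wins_open_time']}/{report['n_seeds']}")
print(f"mean volume saving: {report['volume_saving_pct_mean']:.1f}% "
      f"(sd {report['volume_saving_pct_sd']:.2f})")
# The average controller pours water on the already-saturated zone while the
# global mean still reads dry; the per-zone fuzzy controller avoids that
# waste and regulates with a finer actuation quantum.
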