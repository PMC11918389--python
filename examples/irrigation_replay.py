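"""Replay the packaged soil-bed sensor scenarios through both controllers.

The fuzzy controller decides per valve group (sensors 1-3 and 4-6), so it
shuts the wet zone while the dry zone keeps watering; the average-value
controller ties both valves to the global mean.  The four-day accounting
compares the two runs' dispensed volumes.
"""

from agriflow.irrigation_control import (
    FUZZY_SCENARIO_ROWS,
    AVERAGE_SCENARIO_ROWS,
    SensorFrame,
    compare_runs,
    reference_ledgers,
    replay_trace,
)

frames = [SensorFrame(readings=r) for r, *_ in FUZZY_SCENARIO_ROWS]
commands = replay_trace(frames, "fuzzy")
print("fuzzy replay (row: group means -> valve steps):")
for frame, cmd in list(zip(frames, commands))[7:10]:
    means = ", ".join(f"{m:6.1f}" for m in frame.group_means())
    print(f"  [{means}] -> steps {cmd.steps}")

avg_frames = [SensorFrame(readings=r) for r, _, _ in AVERAGE_SCENARIO_ROWS]
avg_cmds = replay_trace(avg_frames, "average")
print(f"average controller: {sum(c.on[0] for c in avg_cmds)}/20 rows ON")

avg, fuz = reference_ledgers()
report = compare_runs(avg, fuz)
print(f"four-day volumes: average {avg.total_volume_ml:.2f} mL, "
      f"fuzzy {fuz.total_volume_ml:.2f} mL")
print(f"water saved by fuzzy control: {report['saved_ml']:.2f} mL "
      f"({report['saved_pct']:.2f}%)")
# Valve steps run 0 (closed) to 32 (fully open); a group mean above ~454
# raw counts reads as dry and opens its valve fully.
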