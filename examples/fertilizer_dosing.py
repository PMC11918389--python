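"""Convert NPK deficits to Urea/TSP/MOP doses and print the reference chart.

A deficit measured in mg/kg converts to kg/ha through the sampled soil layer
(kg/ha = mg/kg x thickness x density / 10) and then to product mass through
the nutrient fractions (urea 46% N, TSP 20% P, MOP 60% K).
"""

from agriflow.fertilizer_plan import build_chart, recommend

plan = recommend({"n": 25.0, "p": -4.0, "k": 12.0})
print("deficits N=25, P=-4, K=12 mg/kg ->", plan.as_dict())

chart = build_chart()
print("\nreference dosing chart (kg/ha):")
print(chart.to_string(index=False))
# A negative deficit means the soil already exceeds the requirement, so the
# product is marked N/A; doses scale linearly with the deficit.
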