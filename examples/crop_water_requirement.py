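"""Daily crop water requirement for a 100 m² tomato plot.

Uses the regional April reference evapotranspiration ET0 = 5.5 mm/day and
the mid-season tomato crop coefficient; also shows ET0 computed from a
synthetic weather record via the FAO-56 Penman-Monteith equation.
"""

from agriflow.soilbed_sim import generate_weather
from agriflow.water_requirement import (
    WeatherRecord,
    daily_water_requirement,
    kc_for_stage,
    penman_monteith_et0,
    truncate2,
)

kc = kc_for_stage("tomato", "medium")
req = daily_water_requirement("tomato", "medium", et0=5.5, area_m2=100.0)
print(f"kc(tomato, medium)   = {kc}")
print(f"ET_crop              = {truncate2(req.etcrop)} mm/day (kc x ET0 = {kc} x 5.5)")
print(f"daily volume (100m2) = {req.volume_l_day:.0f} L/day")

rice = daily_water_requirement("rice", "medium", et0=5.5, area_m2=100.0)
print(f"rice, same plot      = {rice.volume_l_day:.0f} L/day")

w = WeatherRecord(**generate_weather(n_days=1, seed=3).iloc[0].to_dict())
print(f"ET0 from one synthetic weather record: {penman_monteith_et0(w):.2f} mm/day")
# 1 mm of evapotranspiration over 1 m^2 equals 1 L, so a 6.3 mm/day crop
# demand over 100 m^2 is 630 L of irrigation water per day.
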