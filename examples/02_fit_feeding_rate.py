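"""Fit-to-weight: solve the feeding rate that hits a weight-at-age target.

Recovers, by bisection on the daily engine, the constant annual feeding rate
p that takes a 6573 g adult lake trout to 6980 g in one year — the fixed
endpoints used for the age-specific consumption comparison.
"""

from thermoniche import default_models, fit_p_year, load_species, simulate
from thermoniche.io import packaged_diet
from thermoniche.scenarios import TemperatureScenario

params = load_species("lake_trout")
diet = packaged_diet("lake_trout")
ed = default_models()["lake_trout"]
nodes = [2.8, 3.8, 4.9, 6.1, 6.9, 7.1, 9.3, 9.5, 5.4, 3.5, 2.5, 2.3, 2.7]
scenario = TemperatureScenario.from_nodes("observed", params.sim_start, nodes)

start_w, end_w = params.age_specific_endpoints
p = fit_p_year(start_w, end_w, scenario.daily, diet, ed, params)
check = simulate(start_w, scenario.daily, [p], diet, ed, params).final_weight

print(f"target   : {start_w:.0f} g -> {end_w:.0f} g in one year")
print(f"fitted p : {p:.4f}  (fraction of maximum consumption)")
print(f"check    : re-simulated end weight {check:.2f} g")
# p is the feeding rate: the fraction of the temperature- and size-limited
# maximum ration the fish must actually eat to realise the observed growth.
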