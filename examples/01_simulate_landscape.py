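"""Generate a synthetic monthly landscape and sample a virtual species.

Builds the default study landscape (60x60 grid of 25-km cells, 3 years, seven
monthly environmental variables with engineered collinearity and a seasonal
crop layer), then samples thinned presence records from a cold-limited virtual
species whose true response optima are known.
"""

import numpy as np

from seasonsdm import LandscapeConfig, generate_env_stack, sample_occurrences
from seasonsdm.synthgrid import default_virtual_species

config = LandscapeConfig(seed=1)
stack = generate_env_stack(config)
species = default_virtual_species()
occurrences = sample_occurrences(species, stack, {m: 50 for m in range(1, 13)}, seed=2)

print(f"layers generated: {len(stack.layers)} "
      f"({len(stack.variables)} variables x years x months)")
print(f"variables: {', '.join(stack.variables)}")

july_max = stack.get_layer("MAXTEMP", 2014, 7).ravel()
july_min = stack.get_layer("MINTEMP", 2014, 7).ravel()
print(f"engineered collinearity, July: r(MAXTEMP, MINTEMP) = "
      f"{np.corrcoef(july_max, july_min)[0, 1]:.3f}")
print(f"crop layer in November all zero: {bool((stack.get_layer('RFD', 2014, 11) == 0).all())}")

print(f"\ntrue species optima: { {k: round(v, 2) for k, v in species.known_optima.items()} }")
print(f"presences sampled: {len(occurrences)} "
      f"({occurrences.groupby('month').size().min()}-"
      f"{occurrences.groupby('month').size().max()} per month, all years pooled)")

# the suitable area (probability > 0.5) expands into mid-summer and contracts
area = {m: np.mean([(species.suitability_grid(stack, y, m) > 0.5).mean()
                    for y in config.years]) for m in (5, 6, 7, 8, 9, 10)}
print("suitable-area fraction by month:",
      {m: round(a, 2) for m, a in area.items()})
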