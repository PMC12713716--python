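"""Niche-dynamics comparison between outbreak and non-outbreak months.

Pools the environments available within 500 km of any presence, fits a 2-axis
PCA niche space, estimates kernel occurrence densities for the outbreak
(June-September) and non-outbreak periods on a shared grid, and computes the
stability / expansion / unfilling indices within the analog environment.
Per-variable occupancy profiles show which axes drive the differentiation.
"""

from seasonsdm import LandscapeConfig, generate_env_stack, sample_occurrences
from seasonsdm.envio import extract_env
from seasonsdm.nichedyn import (
    OUTBREAK_MONTHS,
    buffer_background,
    density_grid,
    fit_niche_space,
    niche_dynamics,
    variable_occupancy,
)
from seasonsdm.synthgrid import default_virtual_species

VARIABLES = ["MINTEMP", "PRECIPI", "EVAPO", "NDVI", "RFD"]

stack = generate_env_stack(LandscapeConfig(seed=1))
species = default_virtual_species()
presences = sample_occurrences(species, stack, {m: 50 for m in range(1, 13)}, seed=2)

background = buffer_background(presences, stack, VARIABLES, radius_km=500.0)
space = fit_niche_space(background, VARIABLES)
print(f"background cells pooled: {len(background)}")
print(f"PCA axes explain {space.explained_variance_ratio[0]:.0%} and "
      f"{space.explained_variance_ratio[1]:.0%} of environmental variance")

cov = extract_env(stack, presences, VARIABLES)
bg_scores = space.transform(background)
out_p = cov["month"].isin(OUTBREAK_MONTHS)
out_b = background["month"].isin(OUTBREAK_MONTHS).to_numpy()
g_out = density_grid(space.transform(cov[out_p]), bg_scores[out_b],
                     period="outbreak", window_scores=bg_scores)
g_non = density_grid(space.transform(cov[~out_p]), bg_scores[~out_b],
                     period="non_outbreak", window_scores=bg_scores)

d = niche_dynamics(g_out, g_non)
print(f"\nstability {d.stability:.2f} + expansion {d.expansion:.2f} = 1 "
      f"(fractions of the non-outbreak occupied niche)")
print(f"unfilling {d.unfilled:.2f} (fraction of the outbreak niche unused "
      f"in non-outbreak months)")

print("\nper-variable occupancy (fraction of the gradient occupied per period):")
for var in VARIABLES:
    try:
        curves = variable_occupancy(
            {"outbreak": cov.loc[out_p, var].to_numpy(),
             "non_outbreak": cov.loc[~out_p, var].to_numpy()},
            {"outbreak": background.loc[out_b, var].to_numpy(),
             "non_outbreak": background.loc[~out_b, var].to_numpy()},
            var,
        )
    except Exception as exc:
        print(f"  {var:8s} skipped ({type(exc).__name__})")
        continue
    seg = curves.occupied_segments(level=0.05)
    print(f"  {var:8s} outbreak {seg['outbreak'].mean():.2f}  "
          f"non-outbreak {seg['non_outbreak'].mean():.2f}  "
          f"overlap {seg['overlap'].mean():.2f}")
print("\nA positive expansion with positive unfilling means the two periods")
print("occupy partly different environments - here driven by the seasonal")
print("temperature and crop cycles, not by a change in species preference.")
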