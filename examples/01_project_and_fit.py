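"""Project synthetic specimens onto the Gulf Coast transect and fit the cline.

Simulates 78 binary haplotype observations (the study-scale sample)
whose eastern-clade frequency follows Phi(m*X + b) along the packaged
Key Largo -> Lakeland GA -> east Texas transect, places each on the
transect, projects it back, and fits the probit cline by maximum
likelihood.
"""

from hybridcline import (
    GeoPoint, fit_probit_cline, derive_cline_stats, project_point,
    simulate_cline_specimens, ClineObservation,
)
from hybridcline.geo import default_transect, point_at

transect = default_transect()
print(f"transect: {len(transect.waypoints)} waypoints, "
      f"{transect.total_length_km:.1f} km total")

obs = simulate_cline_specimens(m=0.00145, b=-0.6512, n=78,
                               x_range=(0.0, transect.total_length_km), seed=42)

# round-trip each specimen through geographic coordinates
projected = []
for o in obs:
    p = point_at(transect, o.x)
    pos = project_point(transect, GeoPoint(p.latitude, p.longitude))
    projected.append(ClineObservation(pos.distance_km, o.y))

fit = fit_probit_cline(projected)
stats = derive_cline_stats(fit)
print(f"converged: {fit.converged}  (n={fit.n_obs}, logL={fit.log_likelihood:.2f})")
print(f"m = {fit.m:.6f} /km (SE {fit.standard_errors[0]:.6f})")
print(f"b = {fit.b:.4f}   (SE {fit.standard_errors[1]:.4f})")
print(f"center          = {stats.center_km:.1f} km from the southern terminus")
print(f"max slope       = {stats.max_slope_per_km:.3g} per km")
print(f"20-80% width    = {stats.width_20_80_km:.1f} km")
print("\nThe center is where the eastern-clade frequency crosses 50%;")
print("the width is the distance over which it rises from 20% to 80%.")
print("With only 78 specimens, estimates scatter noticeably around the")
print("generating values (m=0.00145, b=-0.6512 -> center 449.1, width 1158.6).")
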