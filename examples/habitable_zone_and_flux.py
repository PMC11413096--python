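"""Habitable orbital distances and surface fluxes across stellar types.

For a range of stars from the coolest M-dwarfs to a Sun-like G star, compute
the habitable-zone boundaries (equilibrium planetary temperature between the
273 K ice line and 373 K steam line) and the band-integrated flux a planet
at the mid habitable distance receives.
"""

from exoantenna import StellarModel, habitable_distances, planet_flux

STARS = [(2300, 0.117), (2800, 0.254), (3300, 0.299),
         (3800, 0.613), (4800, 0.775), (5800, 0.936)]

print(f"{'T_s (K)':>8} {'R_s (Rsun)':>11} {'a_min':>7} {'a_mid':>7} "
      f"{'a_max':>7}  {'power (W/m^2)':>13}")
for t_star, r_star in STARS:
    star = StellarModel.from_solar(t_star, r_star)
    hz = habitable_distances(star)
    flux = planet_flux(star)  # blackbody at a_mid, 200-2500 nm
    print(f"{t_star:8d} {r_star:11.3f} {hz.a_min:7.3f} {hz.a_mid:7.3f} "
          f"{hz.a_max:7.3f}  {flux.integrated_power():13.1f}")

print("\nDistances are in astronomical units. The integrated power is the")
print("200-2500 nm band at the mid habitable distance; it is similar across")
print("stars by construction (that is what 'habitable' means here), but its")
print("spectral distribution differs drastically: cool stars emit almost")
print("nothing in the 400-700 nm oxygenic photosynthesis window.")
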