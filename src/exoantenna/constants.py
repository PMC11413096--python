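"""Physical constants and unit conversions used throughout the package.

CODATA values come from :mod:`scipy.constants`.  Astronomical conversions
follow the IAU nominal values, which reproduce the habitable-distance
bookkeeping most faithfully (see docs/methods.md).
"""

from scipy.constants import c, h, k as k_B  # noqa: F401  (re-exported)

#: IAU nominal solar radius, m.
R_SUN = 6.957e8

#: Astronomical unit, m.
AU = 1.496e11

#: Metres per nanometre.
NM = 1e-9

#: Planetary "ice line" temperature bounding the habitable zone, K.
T_ICE = 273.0

#: Planetary "steam line" temperature bounding the habitable zone, K.
T_STEAM = 373.0

#: Wien displacement constant, nm K (peak of the Planck spectral radiance).
WIEN_NM_K = 2.897771955e6

#: hc in eV nm, handy for quick enthalpy checks.
HC_EV_NM = 1239.841984
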