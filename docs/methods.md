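# Methods

## The model

`exoantenna` implements a thermodynamic kinetic model of a generalized
photosynthetic supercomplex: a central reaction centre (RC) fed by an
antenna of light-harvesting (LHC) sub-units, driven by an arbitrary
irradiant spectral flux f_p(λ).  The model deliberately carries no
molecular detail; its only ingredients are pool sizes, Gaussian absorption
bands, a handful of rate constants, and free-energy bookkeeping.

### Light environment

A star is characterized by (T_s, R_s).  The built-in light source is the
hemispheric blackbody surface flux I_s(λ) = π B(λ, T_s) (W m⁻² nm⁻¹);
external spectra (e.g. PHOENIX exports) are loaded from two-column text and
treated as opaque inputs.  The flux at an orbit a_sp follows radiative
equilibrium, f_p = (R_s/a_sp)² I_s.  Habitable orbital distances come from
the equilibrium-temperature relation a_sp = (R_s/2)(T_s/T_p)², evaluated at
the ice line (T_p = 273 K, outer edge) and steam line (373 K, inner edge);
the default operating point is their midpoint.  No albedo, greenhouse or
atmospheric correction is applied (an atmospheric transmission spectrum can
be multiplied in explicitly); for the Sun this places Earth's orbit
slightly outside the computed zone, which is expected of the bare relation.

Unit conversions use the IAU nominal values 1 R_⊙ = 6.957×10⁸ m and
1 au = 1.496×10¹¹ m.  With these, 21 of the 24 habitable-distance entries
of the reference stellar table round to the printed 3 decimals; the
remaining three (2600 K mid, 3300 K min, 4800 K min) differ by ≤ 6×10⁻⁴ au,
which no shared constant choice removes — the discrepancies are consistent
with source radii carrying more digits than the 3 printed.  The acceptance
check therefore asserts agreement within one unit in the last printed
digit (10⁻³ au).

### Capture, transfer, trapping

Each pigment pool i has a Gaussian absorption band A_i(λ) with peak λ_p^i,
standard deviation w (default 10 nm) and integrated cross-section
σ_int = σ_peak·w·√(2π), with σ_peak = 10⁻²⁰ m² by default (the measured
magnitude for chlorophyll-like pigments; the config parameter is the peak
value so the user-facing number matches that magnitude).  The per-pigment
photon capture rate is

    γ_i = ∫ (λ/hc) f_p(λ) A_i(λ) dλ   [photons s⁻¹ per pigment],

evaluated by trapezoid quadrature on the flux grid.  (Dimensional analysis
fixes the units as per-pigment capture rates; a per-area reading is not
consistent with A in m².)

Inter-pool transfer donor → acceptor is

    k_{i→j} = k_hop · ρ(i, j) · f(ΔF_{i→j}),
    ΔF = ΔH − TΔS,   ΔH = hc(1/λ_j − 1/λ_i),   ΔS = k_B ln(N_j/N_i),

with f(ΔF) = 1 for ΔF ≤ 0 and exp(−ΔF/k_BT) otherwise, so every connected
pair obeys detailed balance k_fwd/k_bwd = exp(−ΔF/k_BT) exactly (verified
to 1e-12 by property tests).  ΔS is the single-excitation limit of the
binomial-multiplicity entropy, whose general-occupancy form is also
implemented (`delta_S_general`).  ρ is the overlap of the two unit-area
lineshapes, the degree of energetic resonance between donor and acceptor.

**Overlap convention.**  Two conventions are implemented.  The *raw* form
uses the lineshape-product integral directly (nm⁻¹, multiplied by a 1 nm
reference), so iso-energetic equal-width pairs at w = 10 nm transfer at
k_hop/(2w√π) ≈ k_hop/35.  The *normalized* form divides by the
self-overlap of a band of width √(w_i w_j), so iso-energetic pairs transfer
at exactly k_hop.  The raw form is the default: it is the literal
density-of-states construction, and it is the convention under which the
model's benchmark behaviour holds — a single chain of small sub-units then
tops out below 20 electrons s⁻¹ (the normalized form reaches ≈ 63 s⁻¹,
which contradicts the known 1D-antenna bound), and the single-pool optimum
lands at 658–659 nm.  The trade-off is that k_hop⁻¹ = 10 ps is then the
*bare* hop time, with effective iso-energetic transfer at ≈ 350 ps;
`raw_overlap=False` restores the other reading.  Overlap integrals are
evaluated by trapezoid rule on a dedicated 0.05 nm grid spanning both bands
± 6 widths, cached per band pair, and match the closed-form Gaussian
product integral to better than 0.1%.

Default rate constants: k_hop⁻¹ = 10 ps, k_diss⁻¹ = 1 ns (all
non-photochemical decay), k_trap⁻¹ = 5 ps (oxygenic RC charge separation),
k_out⁻¹ = 10 ms (the water-oxidation / quinone-reduction cycle, the rate
limit of the whole machine).  k_diss = 0 is accepted as the ideal-pigment
limit, in which the quantum efficiency is exactly 1.  The thermodynamic
temperature defaults to 300 K (ambient biology); it enters only through
β = 1/k_BT.

### Topologies

* *illustrative*: one antenna pool of N_p pigments coupled to the RC
  (N_r = 10, λ_r = 680 nm).  Pools ≫ 100 pigments violate the
  instantaneous intra-pool equilibration assumption; the builders warn but
  allow them, since the family exists to illustrate diminishing returns.
* *branched / modular*: N_b unbranched chains ("branches") of identical
  sub-units radiating from the RC; shell k is adjacent to shells k ± 1 and
  shell 0 to the RC.  Branches do not interconnect — a lattice would let
  the exciton wander rather than funnel.  N_b = 1, 6, 12 can be read as
  1D/2D/3D packings.
* *funnel*: the branched topology with shell k blue-shifted to
  λ_inner − k·Δλ, making inward transfer enthalpically downhill
  (phycobilisome-like).

The RC is never photo-excited directly (it holds < 1% of the pigments).
Every builder output is validated: connected, symmetric adjacency, no
self-edges, shell-0 adjacency to the RC, N_p = Σ N_i.

### Steady state and observables

Dissipation and trapping are orders of magnitude faster than photon
arrival, so at most one exciton is present at a time.  The state space is
(exciton location) × (trap open/closed) with location ∈ {none, each
sub-unit, RC} — 2(N_LHC + 2) states.  Transitions: capture (γ_i N_i from
the empty states into sub-unit i, allowed whether the trap is open or
closed), dissipation (k_diss from any excited location), transfer along
edges, trapping (RC, open) → (empty, closed) at k_trap, and electron
output (·, closed) → (·, open) at k_out.  A trapping term that would
require two simultaneous excitations is dropped, consistent with the
single-excitation truncation; dissipation of the charge-separated state is
neglected.

The stationary distribution solves Qπ = 0 with one balance row replaced by
normalization (dense LU; systems here are ≤ a few hundred states).  The
residual is checked on the nondimensionalized generator Q/max|Q| to 1e-10
— an absolute s⁻¹ residual criterion would be meaningless next to rates of
10¹¹ s⁻¹.  Entries are clipped at 0 and renormalized (negative excursions
are at rounding level).  Observables: ⟨n_t⟩ (trap-closed probability),
ν_e = k_out⟨n_t⟩, ν_e/N_p with N_p the *antenna* pigment count, and the
absolute quantum efficiency

    φ_e = lim_{γ→0} ν_e / (ν_e + k_diss(⟨n_r⟩ + Σ⟨n_i⟩)),

evaluated numerically by scaling all γ by s = 10⁻⁶ and halving until the
yield changes by < 10⁻⁶ relative; in the linear regime the yield is
scale-free, so this converges immediately.

A Gillespie continuous-time Markov-chain simulation over the identical
state space and rates acts as an independent oracle: time-weighted
occupancies and the empirical electron rate (trap-reopening events per
unit time) with batch-means standard errors (20 batches) agree with the
linear solve within Monte-Carlo error in the tests.

## Sweeps and reported optima

The sweep drivers scan λ_p × size (illustrative, modular) or Δλ × size
(funnel) and tabulate ν_e, φ_e and ν_e/N_p in a long-form table with a
provenance block (grids, parameters, config hash, package version).  Grid
defaults: λ 620–700 nm step 1 nm; Δλ 0–30 nm step 1 nm; sizes log-spaced
1–1000 pigments (illustrative) or 1–10 shells per branch; these sizes keep
a full sweep under a few seconds on one core while resolving the optima at
grid resolution.  Optima are reported at grid resolution, never
interpolated; ties break toward the smaller wavelength/shift and are
flagged, and the one-step neighbourhood is attached so flat ridges are
visible.  Rows are flagged when ν_e ≥ 50 s⁻¹ (half the saturated output at
default k_out) and when ν_e/N_p > 0.03 s⁻¹ (an approximate lower limit for
oxygenic photosynthesis on Earth).

Under a 5800 K blackbody at the mid habitable distance with the default
parameters the package finds: single-pool optimum λ_p = 658 nm; modular
(6 branches, 100-pigment sub-units) optimum λ_p = 659 nm; funnel optimal
per-shell shift Δλ = 11 nm; a 1-branch small-sub-unit antenna peaks below
16 electrons s⁻¹.  The single-pool and modular optima sit at the
free-energy corner where the antenna→RC enthalpy drop exactly cancels the
entropy penalty, hc(1/λ_r − 1/λ) = −k_BT ln(N_i/N_r) → λ ≈ 659 nm for
N_i/N_r = 10 at 300 K.  These optima are remarkably rigid: they are
unchanged under rescaling k_hop or k_diss by more than an order of
magnitude and under swapping the flux between 2300 K, 3300 K, 5800 K
blackbodies or a flat spectrum, and they shift with the lineshape width w
only as the overlap-vs-penalty balance dictates.  The ν_e ridges around
them are flat to well under 1%, so reading an optimum off a heatmap to
better than a few nm is not meaningful — reported optima should always be
interpreted together with their neighbourhood values.

## What the blackbody stand-in does and does not capture

The blackbody source reproduces the broadband colour of a stellar
photosphere and hence everything the thermodynamic terms care about, but
no line structure (molecular bands of real M-dwarf spectra, Fraunhofer
lines).  Since a 10 nm-wide pigment can only resolve ~10 nm features,
smooth-spectrum conclusions (optima positions, saturation behaviour,
funnel-vs-modular ordering) transfer to realistic spectra, but *absolute*
electron outputs for cool stars depend on how much flux their real spectra
put in the 600–700 nm window and are not reproduced here.  Tests passing
under the blackbody say nothing about those absolute M-dwarf numbers.

## Numerical choices and degenerate inputs

* Quadratures are trapezoid on the supplied grids; the default wavelength
  grid is 200–2500 nm with 4000 points (covers PAR and the NIR window).
* Resampling is bin-averaging (smoothing and downsampling in one pass)
  onto equal-width bins, with centroid wavelengths; empty bins fall back
  to linear interpolation at the bin centre.  Resampling to the input
  length is the identity, making the operation idempotent.
* Transmission spectra are linearly interpolated onto the flux grid and
  treated as opaque (0) outside their own range — conservative and
  explicit.
* Dark systems (γ = 0) are handled throughout: the stationary state is
  the open ground state; the Gillespie simulation detects the absorbing
  state and stops; φ_e is undefined and raises.
* Rates underflowing to IEEE subnormals (overlaps of bands hundreds of nm
  apart) lose the detailed-balance identity at the 1e-11 level purely
  through subnormal rounding; the property tests exclude that regime.

## Known limitations

* Single-excitation truncation only; no multi-exciton states, no
  annihilation, no transient (time-dependent) solutions.
* No Stokes shift or distinct fluorescence lineshape; no vibronic
  sidebands.
* No lattice topologies or heterogeneous branch lengths.
* The choice between raw and normalized overlap rescales all transfer
  rates by ~1/35; observables that depend on the transfer/dissipation
  ratio (1D chain throughput, φ_e magnitudes) depend on this convention,
  and both are exposed precisely because the literature construction is
  dimensionally ambiguous.
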