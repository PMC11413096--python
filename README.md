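# exoantenna

Thermodynamic models of photosynthetic light-harvesting antennae under
arbitrary stellar spectral fluxes.

Could oxygenic photosynthesis work around stars very different from the
Sun?  The answer hinges less on raw photon supply than on a thermodynamic
constraint: harvesting light means concentrating energy absorbed over a
large antenna into a tiny reaction centre (RC), which costs entropy.
`exoantenna` is a small library for exploring that constraint.  It builds
antenna–RC kinetic networks, drives them with a stellar flux (a built-in
blackbody stand-in, or any loaded spectrum), solves the steady state of
the resulting Markov chain, and sweeps antenna architectures — single
pools, branched "modular" arrays of identical sub-units (plant-like), and
enthalpy "funnels" of progressively blue-shifted shells
(phycobilisome-like) — to find which structures are viable under which
stars.  It is aimed at quantitative biologists and astrobiology-curious
physicists who want a transparent, fully inspectable model rather than a
molecular simulation.

## The model in brief

A photosystem is a set of pigment pools: LHC sub-units (N_i pigments,
Gaussian absorption band peaking at λ_p^i, width w ≈ 10 nm) around an RC
(N_r = 10, λ_p^r = 680 nm for an oxygenic RC) holding a single trap.
Photons are captured at γ_i = ∫ (λ/hc) f_p(λ) A_i(λ) dλ per pigment; the
resulting exciton hops between connected pools at

k_{i→j} = k_hop · ρ(i,j) · f(ΔF_{i→j}),  ΔF = ΔH − TΔS,

where ΔH = hc(1/λ_j − 1/λ_i) is the excitation-energy drop,
ΔS = k_B ln(N_j/N_i) the pool-size entropy, ρ the donor–acceptor lineshape
overlap, and f the one-sided Boltzmann penalty (1 downhill, exp(−ΔF/k_BT)
uphill) — so every link obeys detailed balance.  Trapping (5 ps) converts
the RC exciton into a charge-separated state; electron output (10 ms, the
water-oxidation cycle) reopens the trap.  In the single-excitation regime
the steady state is the stationary vector of a small generator matrix, and
the observables are the electron output rate ν_e = k_out⟨n_t⟩ (capped at
k_out = 100 s⁻¹), the low-light quantum efficiency φ_e, and the
per-pigment output ν_e/N_p.  A Gillespie simulation over the same network
validates the solver.  See `docs/methods.md` for the full account.

## Worked example

```python
from exoantenna import (StellarModel, build_illustrative, planet_flux,
                        solve_photosystem)

star = StellarModel.from_solar(5800, 0.936)   # a Sun-like star
flux = planet_flux(star)                      # blackbody at mid habitable distance

graph = build_illustrative(n_pigments=100, lambda_peak=659.0)
res = solve_photosystem(graph, flux)
print(res.nu_e, res.phi_e, res.occ_trap)
```

Running `python examples/single_antenna_solve.py` (the same computation)
prints:

```
electron output nu_e      :   47.986 s^-1 (ceiling k_out = 100)
quantum efficiency phi_e  :   0.4664
output per pigment        :   0.4799 s^-1
trap closed fraction      :   0.4799
```

A 100-pigment antenna at its optimal peak (≈ 659 nm, blue of the RC by
just enough that the enthalpy drop pays the entropy bill of a 100 → 10
pigment transfer) drives the RC to ≈ 48% duty under Sun-like light; about
47% of captured photons become electrons.  The architecture comparison
(`python examples/modular_vs_funnel.py`) shows why funnels matter for cool
stars:

```
T_s = 5800 K: modular nu_e =  86.91 s^-1, funnel nu_e =  91.37 s^-1  ( +5.1%)
T_s = 3300 K: modular nu_e =  78.58 s^-1, funnel nu_e =  84.89 s^-1  ( +8.0%)
T_s = 2300 K: modular nu_e =  47.36 s^-1, funnel nu_e =  56.96 s^-1  (+20.3%)
```

The other examples cover the habitable-zone bookkeeping and the
stochastic-vs-exact solver cross-check.

## Command line

A thin CLI wraps the library for shell use:

```bash
exoantenna spectra hz --tstar 5800 --rstar 0.936
exoantenna spectra blackbody --tstar 3300 --rstar 0.299 --out flux.txt
exoantenna solve --config run.yaml
exoantenna gillespie --config run.yaml --seed 1 --events 50000
exoantenna sweep --family funnel --config run.yaml --out sweepdir/
exoantenna graph dump --config run.yaml
```

One YAML config drives everything; the fully-resolved configuration is
echoed beside results so a run is reproducible from its outputs.

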