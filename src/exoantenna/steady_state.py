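"""Single-excitation steady state of the antenna-RC kinetic network.

The photosystem holds at most one exciton at a time (dissipation and
trapping are always much faster than photon arrival), so the state space is
(exciton location) x (trap open/closed) with location ranging over "no
exciton", each antenna sub-unit, and the RC pigment pool.  The stationary
distribution of the resulting continuous-time Markov chain yields the
observables:

* nu_e  = k_out * <n_t>, the steady-state electron output rate;
* phi_e = low-light limit of nu_e / (nu_e + k_diss * <n_exciton>), the
  absolute quantum efficiency;
* nu_e / N_p, output per antenna pigment (a crude metabolic-cost metric).

A Gillespie stochastic simulation over the same state space serves as an
independent check on the linear-algebra solution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .antenna import RC_ID, PhotosystemGraph
from .photophysics import ThermoParams, excitation_rate, transfer_rate

logger = logging.getLogger(__name__)

__all__ = [
    "EMPTY",
    "StateSpace",
    "RateSet",
    "SteadyStateResult",
    "GillespieResult",
    "enumerate_states",
    "build_rate_set",
    "build_generator",
    "solve_stationary",
    "observables",
    "solve_photosystem",
    "gillespie",
]

#: Location label for "no exciton anywhere in the photosystem".
EMPTY = "empty"

_RESIDUAL_TOL = 1e-10


@dataclass(frozen=True)
class StateSpace:
    """Enumerated (exciton location, trap occupancy) states.

    ``locations`` is (EMPTY, sub-unit ids..., RC); states are every
    (location, trap) pair, 2 * (N_LHC + 2) in total.  Double occupancy
    (an exciton in the antenna *and* one in the RC) is excluded by the
    single-excitation truncation.
    """

    locations: tuple[str, ...]
    states: tuple[tuple[str, int], ...]
    index: dict = field(repr=False, default_factory=dict)

    def __len__(self) -> int:
        return len(self.states)


def enumerate_states(graph: PhotosystemGraph) -> StateSpace:
    """Enumerate the single-excitation state space of a photosystem."""
    locations = (EMPTY, *(s.id for s in graph.subunits), RC_ID)
    states = tuple((loc, t) for loc in locations for t in (0, 1))
    return StateSpace(locations=locations, states=states,
                      index={s: i for i, s in enumerate(states)})


@dataclass(frozen=True)
class RateSet:
    """All rate constants of a photosystem under a given light environment.

    ``gamma`` maps sub-unit id -> photon capture rate per pigment (s^-1);
    ``n_pigments`` maps sub-unit id -> pool size; ``k`` maps ordered
    (donor, acceptor) pairs (sub-unit or RC ids) -> transfer rate (s^-1),
    present only for adjacent pairs.
    """

    gamma: dict
    n_pigments: dict
    k: dict
    thermo: ThermoParams

    def __post_init__(self) -> None:
        for name, d in (("gamma", self.gamma), ("k", self.k)):
            for key, val in d.items():
                if val < 0:
                    raise ValueError(f"negative rate in {name}[{key}] = {val}")


def build_rate_set(graph: PhotosystemGraph, flux=None,
                   thermo: ThermoParams | None = None,
                   raw_overlap: bool = True) -> RateSet:
    """Assemble capture and transfer rates for a photosystem.

    ``flux`` may be None, in which case all capture rates are zero (dark).
    Capture rates are computed once per distinct absorption band and shared
    between identical sub-units.
    """
    thermo = thermo or ThermoParams()
    gamma: dict = {}
    if flux is not None:
        cache: dict = {}
        for s in graph.subunits:
            key = (s.profile.lambda_peak, s.profile.width, s.profile.sigma_peak)
            if key not in cache:
                cache[key] = excitation_rate(flux, s.profile)
            gamma[s.id] = cache[key]
    else:
        gamma = {s.id: 0.0 for s in graph.subunits}

    nodes = {s.id: s for s in graph.subunits}
    nodes[RC_ID] = graph.rc
    k: dict = {}
    for edge in graph.edges:
        a, b = tuple(edge)
        k[(a, b)] = transfer_rate(nodes[a], nodes[b], True, thermo,
                                  raw_overlap=raw_overlap)
        k[(b, a)] = transfer_rate(nodes[b], nodes[a], True, thermo,
                                  raw_overlap=raw_overlap)
    return RateSet(gamma=gamma,
                   n_pigments={s.id: s.n_pigments for s in graph.subunits},
                   k=k, thermo=thermo)


def _transitions(space: StateSpace, rates: RateSet,
                 gamma_scale: float = 1.0) -> list[tuple[int, int, float]]:
    """List of (from_index, to_index, rate) transitions, zero rates dropped."""
    th = rates.thermo
    idx = space.index
    subunits = [loc for loc in space.locations if loc not in (EMPTY, RC_ID)]
    out: list[tuple[int, int, float]] = []

    def add(src, dst, rate):
        if rate > 0:
            out.append((idx[src], idx[dst], rate))

    for t in (0, 1):
        for i in subunits:
            # photon capture populates the antenna (never the RC directly)
            add((EMPTY, t), (i, t), gamma_scale * rates.gamma[i] * rates.n_pigments[i])
            add((i, t), (EMPTY, t), th.k_diss)
        add((RC_ID, t), (EMPTY, t), th.k_diss)
        for (a, b), rate in rates.k.items():
            add((a, t), (b, t), rate)
    # trapping converts the RC exciton into the charge-separated (closed) trap
    add((RC_ID, 0), (EMPTY, 1), th.k_trap)
    # electron output re-opens the trap wherever the exciton is
    for loc in space.locations:
        add((loc, 1), (loc, 0), th.k_out)
    return out


def build_generator(space: StateSpace, rates: RateSet,
                    gamma_scale: float = 1.0) -> np.ndarray:
    """Dense generator Q with d pi / dt = Q pi (columns sum to zero)."""
    n = len(space)
    q = np.zeros((n, n))
    for src, dst, rate in _transitions(space, rates, gamma_scale):
        q[dst, src] += rate
        q[src, src] -= rate
    return q


def solve_stationary(generator: np.ndarray) -> np.ndarray:
    """Stationary distribution of a conservative rate matrix.

    Solves Q pi = 0 with the last balance equation replaced by the
    normalization constraint.  The residual is checked on the
    nondimensionalized generator (Q divided by its largest rate) to a
    tolerance of 1e-10.
    """
    q = np.asarray(generator, dtype=float)
    n = q.shape[0]
    if q.shape != (n, n):
        raise ValueError("generator must be square")
    colsum = np.abs(q.sum(axis=0)).max()
    scale = np.abs(q).max()
    if scale == 0:
        raise np.linalg.LinAlgError("generator is identically zero")
    if colsum > 1e-8 * scale:
        raise ValueError("generator columns do not sum to zero: not conservative")
    a = q.copy()
    a[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    try:
        pi = scipy.linalg.solve(a, b)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - degenerate input
        cond = np.linalg.cond(a)
        raise np.linalg.LinAlgError(
            f"stationary solve failed (condition number {cond:.3e})") from exc
    residual = np.abs(q @ pi).max() / scale
    if residual > _RESIDUAL_TOL:
        raise np.linalg.LinAlgError(
            f"stationary residual {residual:.3e} exceeds {_RESIDUAL_TOL:.0e} "
            f"(condition number {np.linalg.cond(a):.3e})")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


@dataclass(frozen=True)
class SteadyStateResult:
    """Stationary distribution and derived observables."""

    space: StateSpace
    probabilities: np.ndarray
    occ_trap: float
    occ_rc: float
    occ_subunits: dict
    nu_e: float
    nu_e_per_pigment: float
    phi_e: float | None = None

    def as_dict(self) -> dict:
        return {
            "nu_e": self.nu_e,
            "phi_e": self.phi_e,
            "nu_e_per_pigment": self.nu_e_per_pigment,
            "occ_trap": self.occ_trap,
            "occ_rc": self.occ_rc,
            "occ_subunits": dict(self.occ_subunits),
        }


def _marginals(space: StateSpace, pi: np.ndarray):
    occ_trap = sum(p for (loc, t), p in zip(space.states, pi) if t == 1)
    occ_rc = sum(p for (loc, t), p in zip(space.states, pi) if loc == RC_ID)
    occ_sub = {
        loc: float(sum(p for (l2, t), p in zip(space.states, pi) if l2 == loc))
        for loc in space.locations if loc not in (EMPTY, RC_ID)}
    return float(occ_trap), float(occ_rc), occ_sub


def observables(probabilities: np.ndarray, space: StateSpace, rates: RateSet,
                graph: PhotosystemGraph,
                phi_e: float | None = None) -> SteadyStateResult:
    """Derive trap/RC/sub-unit occupancies and output metrics."""
    occ_trap, occ_rc, occ_sub = _marginals(space, probabilities)
    nu_e = rates.thermo.k_out * occ_trap
    n_p = graph.n_antenna_pigments
    return SteadyStateResult(
        space=space, probabilities=probabilities,
        occ_trap=occ_trap, occ_rc=occ_rc, occ_subunits=occ_sub,
        nu_e=nu_e, nu_e_per_pigment=nu_e / n_p, phi_e=phi_e)


def quantum_efficiency(space: StateSpace, rates: RateSet,
                       rtol: float = 1e-6, max_halvings: int = 60) -> float:
    """Absolute quantum efficiency: the low-light limit of the output yield.

    Evaluated numerically by scaling all capture rates by s (starting at
    1e-6) and halving s until the yield nu_e / (nu_e + k_diss <n_exc>)
    changes by less than ``rtol`` relatively; the yield is scale-free once
    the response is linear, so this converges almost immediately.
    """
    if all(g == 0 for g in rates.gamma.values()):
        raise ValueError("quantum efficiency is undefined in the dark (all gamma = 0)")
    th = rates.thermo

    def ratio(scale: float) -> float:
        pi = solve_stationary(build_generator(space, rates, gamma_scale=scale))
        occ_trap, occ_rc, occ_sub = _marginals(space, pi)
        nu = th.k_out * occ_trap
        loss = th.k_diss * (occ_rc + sum(occ_sub.values()))
        return nu / (nu + loss) if (nu + loss) > 0 else 0.0

    scale = 1e-6
    prev = ratio(scale)
    for _ in range(max_halvings):
        scale *= 0.5
        cur = ratio(scale)
        if abs(cur - prev) <= rtol * max(abs(prev), 1e-300):
            return cur
        prev = cur
    logger.warning("quantum efficiency limit did not converge to %g", rtol)
    return prev


def solve_photosystem(graph: PhotosystemGraph, flux=None,
                      thermo: ThermoParams | None = None,
                      gamma_scale: float = 1.0,
                      compute_phi: bool = True,
                      raw_overlap: bool = True) -> SteadyStateResult:
    """End-to-end solve: rates -> generator -> stationary state -> observables."""
    rates = build_rate_set(graph, flux, thermo, raw_overlap=raw_overlap)
    space = enumerate_states(graph)
    pi = solve_stationary(build_generator(space, rates, gamma_scale))
    phi = None
    if compute_phi and any(g > 0 for g in rates.gamma.values()):
        phi = quantum_efficiency(space, rates)
    return observables(pi, space, rates, graph, phi_e=phi)


@dataclass(frozen=True)
class GillespieResult:
    """Time-weighted occupancy estimates from a stochastic trajectory."""

    space: StateSpace
    occupancy: np.ndarray       # fraction of time in each state
    occupancy_se: np.ndarray    # batch-means standard errors
    nu_e: float                 # electron output events / total time
    nu_e_se: float
    electron_events: int
    trap_fill_events: int       # trapping transitions (RC, open) -> (empty, closed)
    n_events: int
    total_time: float

    def occ_trap(self) -> float:
        return float(sum(p for (loc, t), p in zip(self.space.states, self.occupancy)
                         if t == 1))


def gillespie(graph: PhotosystemGraph, rates: RateSet, seed: int,
              n_events: int = 50_000, gamma_scale: float = 1.0,
              n_batches: int = 20) -> GillespieResult:
    """Continuous-time Markov-chain simulation over the same state space.

    Serves as an independent oracle for the linear-algebra steady state.
    Returns time-weighted occupancy fractions with batch-means standard
    errors (``n_batches`` equal-event batches) and the empirical electron
    output rate (trap-reopening events per unit time).
    """
    if n_events < n_batches:
        raise ValueError("n_events must be at least n_batches")
    space = enumerate_states(graph)
    n = len(space)
    trans = _transitions(space, rates, gamma_scale)
    targets: list[np.ndarray] = [np.empty(0, dtype=int) for _ in range(n)]
    cumrates: list[np.ndarray] = [np.empty(0) for _ in range(n)]
    totals = np.zeros(n)
    by_src: dict[int, list[tuple[int, float]]] = {}
    for src, dst, rate in trans:
        by_src.setdefault(src, []).append((dst, rate))
    is_output = np.zeros((n, n), dtype=bool)
    for (loc, t), i in space.index.items():
        if t == 1:
            j = space.index[(loc, 0)]
            is_output[i, j] = True
    trap_src = space.index[(RC_ID, 0)]
    trap_dst = space.index[(EMPTY, 1)]
    for src, pairs in by_src.items():
        targets[src] = np.array([d for d, _ in pairs], dtype=int)
        r = np.array([r for _, r in pairs])
        totals[src] = r.sum()
        cumrates[src] = np.cumsum(r)

    rng = np.random.default_rng(seed)
    state = space.index[(EMPTY, 0)]
    batch_edges = np.linspace(0, n_events, n_batches + 1).astype(int)
    occ_batches = np.zeros((n_batches, n))
    time_batches = np.zeros(n_batches)
    electron_batches = np.zeros(n_batches, dtype=int)
    trap_fills = 0
    batch = 0
    for ev in range(n_events):
        if ev >= batch_edges[batch + 1]:
            batch += 1
        total = totals[state]
        if total == 0:
            logger.warning("absorbing state %s reached after %d events "
                           "(no photon capture); stopping early",
                           space.states[state], ev)
            break
        dt = rng.exponential(1.0 / total)
        occ_batches[batch, state] += dt
        time_batches[batch] += dt
        u = rng.random() * total
        nxt = int(targets[state][np.searchsorted(cumrates[state], u)])
        if is_output[state, nxt]:
            electron_batches[batch] += 1
        if state == trap_src and nxt == trap_dst:
            trap_fills += 1
        state = nxt

    total_time = time_batches.sum()
    if total_time == 0:  # absorbed before any event fired
        occupancy = np.zeros(n)
        occupancy[state] = 1.0
        return GillespieResult(space=space, occupancy=occupancy,
                               occupancy_se=np.zeros(n), nu_e=0.0, nu_e_se=0.0,
                               electron_events=0, trap_fill_events=0,
                               n_events=n_events, total_time=0.0)
    occupancy = occ_batches.sum(axis=0) / total_time
    live = time_batches > 0
    frac = occ_batches[live] / time_batches[live, None]
    occupancy_se = frac.std(axis=0, ddof=1) / np.sqrt(live.sum())
    nu_batches = electron_batches[live] / time_batches[live]
    nu_e = electron_batches.sum() / total_time
    nu_e_se = float(nu_batches.std(ddof=1) / np.sqrt(live.sum()))
    return GillespieResult(space=space, occupancy=occupancy,
                           occupancy_se=occupancy_se, nu_e=float(nu_e),
                           nu_e_se=nu_e_se,
                           electron_events=int(electron_batches.sum()),
                           trap_fill_events=trap_fills,
                           n_events=n_events, total_time=float(total_time))
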