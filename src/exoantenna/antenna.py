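"""Photosystem topology: reaction centre, antenna sub-units, adjacency.

Three antenna families are supported:

* *illustrative* — a single light-harvesting pool of variable size coupled
  to the RC (a deliberately crude architecture with a narrow RC bottleneck);
* *branched / modular* — N_b unbranched chains of identical sub-units
  radiating from the RC (plant-like when sub-units are iso-energetic);
* *funnel* — a branched antenna whose shells are progressively blue-shifted
  moving away from the RC (phycobilisome-like enthalpy funnel).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .photophysics import AbsorptionProfile, absorption_value

logger = logging.getLogger(__name__)

__all__ = [
    "RC_ID",
    "SubUnit",
    "ReactionCentre",
    "PhotosystemGraph",
    "build_illustrative",
    "build_branched",
    "assign_funnel",
    "antenna_absorption_spectrum",
]

#: Node label of the reaction centre in every graph.
RC_ID = "RC"

#: Sub-units above this size violate the fast intra-pool equilibration
#: assumption and should be modelled as blocks of smaller identical units.
EQUILIBRATION_LIMIT = 100


@dataclass(frozen=True)
class SubUnit:
    """A light-harvesting sub-unit: a pool of equivalent pigment states.

    ``shell`` is the hop distance from the RC (0 = adjacent); ``branch``
    indexes the chain the sub-unit belongs to.
    """

    id: str
    n_pigments: int
    profile: AbsorptionProfile
    shell: int = 0
    branch: int = 0

    def __post_init__(self) -> None:
        if self.n_pigments < 1:
            raise ValueError(f"sub-unit {self.id}: n_pigments must be >= 1")
        if self.n_pigments > EQUILIBRATION_LIMIT:
            logger.warning(
                "sub-unit %s has %d pigments (> %d); intra-pool equilibration "
                "is assumed instantaneous, which becomes unrealistic for "
                "pools this large", self.id, self.n_pigments, EQUILIBRATION_LIMIT)


@dataclass(frozen=True)
class ReactionCentre:
    """The RC: a small pigment pool feeding a single charge-separation trap."""

    n_pigments: int = 10
    profile: AbsorptionProfile = field(
        default_factory=lambda: AbsorptionProfile(lambda_peak=680.0))
    n_trap: int = 1

    def __post_init__(self) -> None:
        if self.n_pigments < 1:
            raise ValueError("RC n_pigments must be >= 1")
        if self.n_trap != 1:
            raise ValueError("the RC carries exactly one trap state")


@dataclass(frozen=True)
class PhotosystemGraph:
    """RC + antenna sub-units + symmetric adjacency.

    The RC is never photo-excited directly (it holds < 1% of the pigments in
    any realistic photosystem); photons enter through the antenna only.
    """

    rc: ReactionCentre
    subunits: tuple[SubUnit, ...]
    edges: frozenset[frozenset[str]]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subunits]
        if len(set(ids)) != len(ids):
            raise ValueError("sub-unit ids must be unique")
        if RC_ID in ids:
            raise ValueError(f"'{RC_ID}' is reserved for the reaction centre")
        nodes = set(ids) | {RC_ID}
        for edge in self.edges:
            if len(edge) != 2:
                raise ValueError(f"self-edge or malformed edge: {set(edge)}")
            if not edge <= nodes:
                raise ValueError(f"edge {set(edge)} references unknown nodes")
        g = self.to_networkx()
        if not nx.is_connected(g):
            raise ValueError("photosystem graph must be connected")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_node(RC_ID)
        g.add_nodes_from(s.id for s in self.subunits)
        g.add_edges_from(tuple(e) for e in self.edges)
        return g

    def subunit(self, subunit_id: str) -> SubUnit:
        for s in self.subunits:
            if s.id == subunit_id:
                return s
        raise KeyError(subunit_id)

    def neighbours(self, node_id: str) -> list[str]:
        return sorted(other for e in self.edges if node_id in e
                      for other in e if other != node_id)

    def connected(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.edges

    @property
    def n_antenna_pigments(self) -> int:
        """Total antenna pigments N_p (the RC pool is not counted)."""
        return sum(s.n_pigments for s in self.subunits)


def _edge(a: str, b: str) -> frozenset[str]:
    if a == b:
        raise ValueError(f"self-edge on {a}")
    return frozenset((a, b))


def build_illustrative(n_pigments: int, lambda_peak: float,
                       width: float = 10.0, sigma_peak: float = 1e-20,
                       rc: ReactionCentre | None = None) -> PhotosystemGraph:
    """A single light-harvesting pool of ``n_pigments`` coupled to the RC."""
    rc = rc or ReactionCentre()
    sub = SubUnit(id="s1", n_pigments=n_pigments,
                  profile=AbsorptionProfile(lambda_peak, width, sigma_peak),
                  shell=0, branch=0)
    return PhotosystemGraph(rc=rc, subunits=(sub,),
                            edges=frozenset({_edge("s1", RC_ID)}))


def build_branched(n_branches: int, n_shells: int, n_pigments_per_subunit: int,
                   lambda_by_shell, width: float = 10.0,
                   sigma_peak: float = 1e-20,
                   rc: ReactionCentre | None = None) -> PhotosystemGraph:
    """N_b identical unbranched chains of sub-units radiating from the RC.

    ``lambda_by_shell`` gives the peak wavelength of each shell (length
    ``n_shells``; shell 0 is adjacent to the RC).  Branches are not
    interconnected: a radial layout keeps the exciton's random walk pointed
    at the RC instead of letting it wander a lattice.
    """
    if n_branches < 1 or n_shells < 1:
        raise ValueError("need n_branches >= 1 and n_shells >= 1")
    lams = [float(x) for x in np.atleast_1d(lambda_by_shell)]
    if len(lams) == 1:
        lams = lams * n_shells
    if len(lams) != n_shells:
        raise ValueError(
            f"lambda_by_shell has {len(lams)} entries for {n_shells} shells")
    rc = rc or ReactionCentre()
    subunits: list[SubUnit] = []
    edges: set[frozenset[str]] = set()
    for b in range(n_branches):
        prev = RC_ID
        for k in range(n_shells):
            sid = f"b{b + 1}s{k + 1}"
            subunits.append(SubUnit(
                id=sid, n_pigments=n_pigments_per_subunit,
                profile=AbsorptionProfile(lams[k], width, sigma_peak),
                shell=k, branch=b))
            edges.add(_edge(prev, sid))
            prev = sid
    return PhotosystemGraph(rc=rc, subunits=tuple(subunits),
                            edges=frozenset(edges))


def assign_funnel(graph: PhotosystemGraph, lambda_inner: float,
                  delta_lambda: float) -> PhotosystemGraph:
    """Impose a progressive blue-shift on the shells of a branched antenna.

    Shell k (0 = adjacent to the RC) gets peak ``lambda_inner - k *
    delta_lambda``; widths, cross-sections, sizes and adjacency are
    untouched.  ``delta_lambda`` must be >= 0 and small enough that every
    resulting peak stays positive.
    """
    if delta_lambda < 0:
        raise ValueError("delta_lambda must be >= 0")
    max_shell = max((s.shell for s in graph.subunits), default=0)
    if lambda_inner - max_shell * delta_lambda <= 0:
        raise ValueError("blue-shift drives the outermost peak non-positive")
    new = tuple(
        replace(s, profile=s.profile.shifted(lambda_inner - s.shell * delta_lambda))
        for s in graph.subunits)
    return PhotosystemGraph(rc=graph.rc, subunits=new, edges=graph.edges)


def antenna_absorption_spectrum(graph: PhotosystemGraph,
                                grid_nm: np.ndarray) -> np.ndarray:
    """Combined antenna absorption on a wavelength grid, normalized to peak 1.

    The curve is the pigment-weighted sum of the sub-unit bands; the RC is
    excluded (it is not photo-excited in this model).
    """
    grid = np.asarray(grid_nm, dtype=float)
    total = np.zeros_like(grid)
    for s in graph.subunits:
        total += s.n_pigments * absorption_value(s.profile, grid)
    peak = total.max()
    return total / peak if peak > 0 else total
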