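"""Signaling-state classification and the inter-state signaling graph.

A cell's signaling state is its derived capability set: which ligands it
can use to send signal (enough free ligand survives cis-inhibition) and
which ligands it can receive from (enough free Notch survives, and the
cell's Fringe status does not block trans-activation by that ligand).
States are computed from component production levels by solving the
multi-ligand cis steady state with Fringe-modified interaction strengths.

The inter-state graph connects state A to state B with ligand l whenever A
sends with l and B receives from l.  For the canonical endpoint
configurations (receptor or ligand strongly dominant, with or without
Fringe) the graph has no self-edges and no directed cycles — a consequence
of strong mutual cis-inhibition, not of the construction: weak-cis
configurations can and do produce self-edges, which are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import networkx as nx

from notchcis.kinetics import (
    FringeConfig,
    KineticParams,
    apply_fringe,
    fringe_preset,
    solve_cis_steady_state,
)

__all__ = [
    "ComponentLevels",
    "SignalingState",
    "StateGraph",
    "classify_state",
    "build_state_graph",
    "classifier_params",
    "canonical_levels",
]

#: default expression levels used for the canonical endpoint states
#: (steady-state concentration units: production/degradation)
HIGH_LEVEL = 20.0
LOW_LEVEL = 0.5


def classifier_params() -> KineticParams:
    """Default kinetics for state classification.

    Strong mutual cis-inhibition: kc*gamma_N = 2/3 model units, far below
    the HIGH expression level of 20, so the dominant component essentially
    eliminates the subordinate one.  A 5-fold Fringe weakening of cis
    association then leaves the depleted partner at ~15% of its unopposed
    level, between the send (20%) and receive (10%) capability thresholds.
    """
    return KineticParams(beta_N=1.0, beta_D=1.0, gamma_N=0.1, gamma_D=0.1,
                         kC_plus=0.3, kC_minus=5.0, kI=5.0,
                         kD_plus=1.0, kD_minus=4.0, kS=1.0)


@dataclass(frozen=True)
class ComponentLevels:
    """Production rates of Notch and each ligand, plus Fringe status."""

    notch_production: float
    ligand_production: Mapping[str, float]
    fringe: FringeConfig = field(default_factory=FringeConfig)

    def __post_init__(self) -> None:
        if self.notch_production < 0 or any(v < 0 for v in self.ligand_production.values()):
            raise ValueError("production rates must be non-negative")


@dataclass
class SignalingState:
    """Free steady-state levels and the derived send/receive capability sets."""

    free_notch: float
    free_ligand: dict[str, float]
    receive_from: frozenset[str]
    send_with: frozenset[str]


@dataclass
class StateGraph:
    """Directed inter-state signaling graph (edges are (sender, receiver, ligand))."""

    states: dict[str, SignalingState]
    edges: list[tuple[str, str, str]]
    graph: nx.MultiDiGraph
    self_edges: list[tuple[str, str]]      # (node, ligand)
    cycles: list[list[str]]                # directed cycles incl. self-loops


def classify_state(levels: ComponentLevels,
                   params: KineticParams | None = None,
                   send_frac: float = 0.2,
                   receive_frac: float = 0.1,
                   blocking_cutoff: float = 0.5,
                   ligand_universe: tuple[str, ...] | None = None) -> SignalingState:
    """Derive a cell's send/receive capabilities from its component levels.

    Per-ligand kinetic parameters are Fringe-modified copies of ``params``
    with the cell's production rates imposed; the multi-ligand cis steady
    state then gives free Notch and free ligands.  The cell

    * receives from ligand l if its free Notch is at least ``receive_frac``
      of the unopposed level beta_N/gamma_N AND its Fringe status does not
      block trans-activation by l (trans factor >= ``blocking_cutoff``);
    * sends with ligand l if free l is at least ``send_frac`` of the
      unopposed level beta_Dl/gamma_D.

    Sending demands a larger surviving fraction than receiving
    (``send_frac`` > ``receive_frac`` by default): a receptor event is
    amplified by downstream signal transduction while sending requires
    substantial surface-ligand density.  Both fractions are relative to
    the cell's own unopposed levels, so the classification is invariant
    under joint rescaling of all production rates and kc.
    """
    if not (0 < send_frac < 1 and 0 < receive_frac < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    params = classifier_params() if params is None else params
    fringe = levels.fringe
    expressed = {l: r for l, r in levels.ligand_production.items()}
    if ligand_universe is None:
        universe = set(expressed) | set(fringe.cis_factor) | set(fringe.trans_factor)
        ligand_universe = tuple(sorted(universe))

    per_ligand = {}
    for lig, beta_D in expressed.items():
        p = replace(params, beta_N=levels.notch_production, beta_D=beta_D)
        per_ligand[lig] = apply_fringe(p, fringe, lig) if _known(fringe, lig) else p
    if per_ligand:
        state = solve_cis_steady_state(per_ligand)
        free_N, free_L = state.N, dict(state.D)
    else:
        free_N = levels.notch_production / params.gamma_N
        free_L = {}

    n_unopposed = levels.notch_production / params.gamma_N
    can_receive = (levels.notch_production > 0
                   and free_N >= receive_frac * n_unopposed)
    receive_from = frozenset(
        l for l in ligand_universe
        if can_receive and fringe.trans(l) >= blocking_cutoff)
    send_with = frozenset(
        l for l, beta_D in expressed.items()
        if beta_D > 0 and free_L[l] >= send_frac * (beta_D / params.gamma_D))
    return SignalingState(free_notch=free_N, free_ligand=free_L,
                          receive_from=receive_from, send_with=send_with)


def build_state_graph(named_levels: Mapping[str, ComponentLevels],
                      params: KineticParams | None = None,
                      **classify_kwargs) -> StateGraph:
    """Classify every named configuration and wire the signaling graph.

    An edge (sender, receiver, ligand) exists iff the sender's state sends
    with that ligand and the receiver's state receives from it.  Self-edges
    and directed cycles are detected and reported, never suppressed.
    """
    if not named_levels:
        raise ValueError("need at least one node")
    states = {name: classify_state(lv, params, **classify_kwargs)
              for name, lv in named_levels.items()}
    g = nx.MultiDiGraph()
    g.add_nodes_from(states)
    edges = []
    for s_name, s in states.items():
        for r_name, r in states.items():
            for lig in s.send_with & r.receive_from:
                g.add_edge(s_name, r_name, ligand=lig)
                edges.append((s_name, r_name, lig))
    self_edges = [(a, lig) for a, b, lig in edges if a == b]
    cycles = [c for c in nx.simple_cycles(nx.DiGraph(g))]
    return StateGraph(states=states, edges=edges, graph=g,
                      self_edges=self_edges, cycles=cycles)


def canonical_levels(high: float = HIGH_LEVEL, low: float = LOW_LEVEL,
                     gamma: float = 0.1) -> dict[str, ComponentLevels]:
    """The eight canonical endpoint configurations.

    For each ligand (Dll1, Jag1), each Fringe status (none, Lfng) and each
    dominance direction (Notch >> ligand, ligand >> Notch), production
    rates are set so the unopposed steady levels are ``high`` and ``low``.
    """
    none, lfng = fringe_preset("none"), fringe_preset("lfng")
    out: dict[str, ComponentLevels] = {}
    for lig in ("Dll1", "Jag1"):
        for fr, tag in ((none, ""), (lfng, "Lfng_")):
            out[f"{tag}{lig}_receiver"] = ComponentLevels(
                notch_production=high * gamma,
                ligand_production={lig: low * gamma}, fringe=fr)
            out[f"{tag}{lig}_sender"] = ComponentLevels(
                notch_production=low * gamma,
                ligand_production={lig: high * gamma}, fringe=fr)
    return out


def _known(fringe: FringeConfig, ligand: str) -> bool:
    return (fringe.identity == "none"
            or ligand in set(fringe.cis_factor) | set(fringe.trans_factor))
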