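"""Scale-free interaction network with opinion-leader roles.

The population interacts on a Barabási–Albert graph: growth starts from
a complete seed graph on ``m + 1`` nodes and every later node attaches
to ``m`` distinct existing nodes sampled proportionally to their current
degree.  High-degree nodes model influential netizens; the top fraction
by degree are designated opinion leaders and carry their own trust
weight in the information dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .config import ConfigError, NetworkParams

__all__ = ["SocialNetwork", "generate_network", "assign_opinion_leaders"]

ROLE_ORDINARY = "ordinary"
ROLE_LEADER = "opinion_leader"


@dataclass
class SocialNetwork:
    """Undirected interaction graph plus per-node roles.

    ``roles`` is a boolean array over node ids 0..N-1; True marks an
    opinion leader.
    """

    graph: nx.Graph
    roles: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.graph.number_of_nodes()
        if self.roles is None:
            self.roles = np.zeros(n, dtype=bool)
        else:
            self.roles = np.asarray(self.roles, dtype=bool)
            if self.roles.shape != (n,):
                raise ConfigError("roles must have one entry per node")

    @property
    def n_agents(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def leaders(self) -> np.ndarray:
        """Node ids of opinion leaders, ascending."""
        return np.flatnonzero(self.roles)

    def degrees(self) -> np.ndarray:
        n = self.n_agents
        deg = np.zeros(n, dtype=np.int64)
        for node, d in self.graph.degree():
            deg[node] = d
        return deg

    # -- text import/export -------------------------------------------

    def save(self, edge_path: str | Path, role_path: str | Path) -> None:
        """Write a two-column tab-separated edge list plus a role sidecar."""
        edges = sorted((min(u, v), max(u, v)) for u, v in self.graph.edges())
        with open(edge_path, "w") as fh:
            for u, v in edges:
                fh.write(f"{u}\t{v}\n")
        with open(role_path, "w") as fh:
            fh.write("node_id\trole\n")
            for node in range(self.n_agents):
                role = ROLE_LEADER if self.roles[node] else ROLE_ORDINARY
                fh.write(f"{node}\t{role}\n")

    @classmethod
    def load(cls, edge_path: str | Path,
             role_path: str | Path | None = None) -> "SocialNetwork":
        graph = nx.Graph()
        with open(edge_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                u, v = line.split("\t")
                graph.add_edge(int(u), int(v))
        graph.add_nodes_from(range(max(graph.nodes) + 1))
        roles = None
        if role_path is not None:
            roles = np.zeros(graph.number_of_nodes(), dtype=bool)
            with open(role_path) as fh:
                header = fh.readline()
                assert header.startswith("node_id")
                for line in fh:
                    node, role = line.split()
                    roles[int(node)] = role == ROLE_LEADER
        return cls(graph=graph, roles=roles)


def generate_network(params: NetworkParams,
                     seed: int | np.random.Generator) -> SocialNetwork:
    """Grow a BA scale-free graph and mark the opinion leaders.

    The seed graph is complete on ``m_attach + 1`` nodes; each later
    node attaches to ``m_attach`` distinct existing nodes, sampled
    without replacement with probability proportional to current degree.
    Deterministic given the seed.  The resulting edge count is exactly
    ``m * (N - m - 1) + m * (m + 1) / 2``.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n, m = params.n_agents, params.m_attach
    if n <= m:
        raise ConfigError("n_agents must exceed m_attach")

    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    # complete seed graph
    seed_nodes = list(range(min(m + 1, n)))
    graph.add_edges_from(
        (u, v) for i, u in enumerate(seed_nodes) for v in seed_nodes[i + 1:]
    )
    # one entry per half-edge: sampling uniformly from this list is
    # degree-proportional sampling over nodes
    repeated: list[int] = [u for u in seed_nodes for _ in range(len(seed_nodes) - 1)]

    for new in range(m + 1, n):
        chosen: set[int] = set()
        while len(chosen) < m:
            pick = repeated[rng.integers(len(repeated))]
            chosen.add(pick)  # rejection gives without-replacement draws
        for target in chosen:
            graph.add_edge(new, target)
        repeated.extend(chosen)
        repeated.extend([new] * m)

    network = SocialNetwork(graph=graph)
    return assign_opinion_leaders(network, params.leader_fraction)


def assign_opinion_leaders(network: SocialNetwork,
                           leader_fraction: float) -> SocialNetwork:
    """Mark the highest-degree nodes as opinion leaders, in place.

    Exactly ``floor(leader_fraction * N)`` nodes get the role; degree
    ties at the cutoff are broken by ascending node id so the set is
    reproducible.
    """
    if not 0.0 <= leader_fraction <= 1.0:
        raise ConfigError("leader_fraction must lie in [0, 1]")
    n = network.n_agents
    n_leaders = int(math.floor(leader_fraction * n))
    deg = network.degrees()
    # stable sort on (-degree, node id): ties resolved by ascending id
    order = np.lexsort((np.arange(n), -deg))
    roles = np.zeros(n, dtype=bool)
    roles[order[:n_leaders]] = True
    network.roles = roles
    return network
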