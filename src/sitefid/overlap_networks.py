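"""Spatial-overlap social networks and community detection.

Two ants that concentrate their visits on the same grid sites have similar
space use.  Pairwise similarity is quantified by the volume of intersection
(VI) between the two normalized site-visit distributions: VI = sum over
sites of min(p_i(s), p_j(s)), which is 1 for identical distributions and 0
for disjoint ones (equivalently, 1 minus the total-variation distance).
The colony's VI matrix defines a weighted undirected graph; modularity-based
community detection (Reichardt-Bornholdt spin-glass, via igraph) splits the
colony into groups with distinctive space-use patterns.  The community
containing the queen is labelled "nurse", the rest "other"; colonies whose
best partition is trivial are marked unpartitioned.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

from .site_fidelity import SiteStats

__all__ = [
    "OverlapNetwork",
    "CommunityPartition",
    "volume_of_intersection",
    "build_network",
    "detect_communities",
    "label_and_map",
    "write_graphml",
]


def volume_of_intersection(n_i, n_j) -> float:
    """Spatial overlap between two per-site visit-count vectors.

    Counts are normalized to utilization distributions; the overlap is the
    sum of per-site minima, in [0, 1].  Inputs may be aligned arrays or
    mappings site -> count (unmentioned sites count 0).
    """
    if isinstance(n_i, (pd.Series, dict)) or isinstance(n_j, (pd.Series, dict)):
        si = pd.Series(n_i, dtype=float)
        sj = pd.Series(n_j, dtype=float)
        sites = si.index.union(sj.index)
        a = si.reindex(sites, fill_value=0.0).to_numpy()
        b = sj.reindex(sites, fill_value=0.0).to_numpy()
    else:
        a = np.asarray(n_i, dtype=float)
        b = np.asarray(n_j, dtype=float)
        if a.shape != b.shape:
            raise ValueError("count vectors must align")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("negative visit counts")
    ta, tb = a.sum(), b.sum()
    if ta == 0 or tb == 0:
        raise ValueError("all-zero visit-count vector")
    return float(np.minimum(a / ta, b / tb).sum())


@dataclass
class OverlapNetwork:
    """Weighted undirected graph of pairwise VI overlaps within one colony."""

    colony_id: str
    graph: nx.Graph

    @property
    def ants(self) -> list[str]:
        return list(self.graph.nodes)

    def strength(self, ant: str) -> float:
        """Weighted degree: sum of incident VI weights."""
        return float(
            sum(d["weight"] for _, _, d in self.graph.edges(ant, data=True))
        )

    def strengths(self) -> pd.Series:
        return pd.Series({a: self.strength(a) for a in self.graph.nodes})


def build_network(colony_stats: Sequence[SiteStats]) -> OverlapNetwork:
    """Complete VI-weighted graph on one colony's ants.

    Zero-weight pairs are dropped (they carry no modularity information);
    vertices keep their caste as an attribute.
    """
    if len(colony_stats) < 2:
        raise ValueError("need at least 2 ants to build a network")
    colonies = {s.colony_id for s in colony_stats}
    if len(colonies) != 1:
        raise ValueError(f"mixed colonies in network build: {sorted(colonies)}")
    g = nx.Graph()
    for s in colony_stats:
        g.add_node(s.ant_id, caste=s.caste)
    for i in range(len(colony_stats)):
        for j in range(i + 1, len(colony_stats)):
            vi = volume_of_intersection(
                colony_stats[i].visit_counts, colony_stats[j].visit_counts
            )
            if vi > 0:
                g.add_edge(colony_stats[i].ant_id, colony_stats[j].ant_id, weight=vi)
    for a in g.nodes:
        g.nodes[a]["strength"] = float(
            sum(d["weight"] for _, _, d in g.edges(a, data=True))
        )
    return OverlapNetwork(colony_id=colonies.pop(), graph=g)


@dataclass
class CommunityPartition:
    """Community assignment of one colony's ants.

    ``membership`` maps ant -> integer community id; ``labels`` maps
    community id -> {"nurse", "other"} once labelled.  A colony whose best
    partition has a single community (or non-positive modularity) is
    unpartitioned and all its ants are labelled accordingly.
    """

    colony_id: str
    membership: dict[str, int]
    modularity: float
    seed: int
    method: str = "spinglass"
    labels: dict[int, str] = field(default_factory=dict)

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    @property
    def partitioned(self) -> bool:
        return self.n_communities > 1 and self.modularity > 0

    def label_of(self, ant: str) -> str:
        if not self.partitioned:
            return "unpartitioned"
        return self.labels.get(self.membership[ant], "unlabelled")


def _spinglass_components(g: ig.Graph, gamma: float) -> list[int]:
    """Spin-glass partition applied per connected component."""
    membership = [0] * g.vcount()
    offset = 0
    for comp in g.connected_components():
        sub = g.subgraph(comp)
        if sub.vcount() <= 3:
            # annealing stalls on tiny components; a connected component of
            # <=3 positive-weight vertices is modularity-optimal as one group
            part = [0] * sub.vcount()
        else:
            clust = sub.community_spinglass(
                weights="weight", gamma=gamma, spins=min(25, sub.vcount())
            )
            part = clust.membership
        for v, m in zip(comp, part):
            membership[v] = offset + m
        offset += max(part) + 1
    return membership


def detect_communities(
    net: OverlapNetwork,
    seed: int = 0,
    gamma: float = 1.0,
    method: str = "spinglass",
) -> CommunityPartition:
    """Modularity-based partition of an overlap network.

    ``method="spinglass"`` uses the annealed Potts-model optimizer from
    igraph (seeded, applied per connected component; isolated vertices form
    singleton communities).  ``method="greedy"`` is a deterministic
    agglomerative-modularity fallback (networkx), useful for quick runs.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    ants = list(g.nodes)
    if method == "spinglass":
        random.seed(seed)
        h = ig.Graph()
        h.add_vertices(ants)
        edges = [(ants.index(u), ants.index(v)) for u, v in g.edges]
        h.add_edges(edges)
        h.es["weight"] = [g.edges[u, v]["weight"] for u, v in g.edges]
        member = _spinglass_components(h, gamma)
    elif method == "greedy":
        communities = nx.community.greedy_modularity_communities(g, weight="weight")
        member = [0] * len(ants)
        for cid, comm in enumerate(communities):
            for a in comm:
                member[ants.index(a)] = cid
    else:
        raise ValueError(f"unknown community method {method!r}")
    membership = dict(zip(ants, member))
    groups: dict[int, set] = {}
    for a, m in membership.items():
        groups.setdefault(m, set()).add(a)
    mod = (
        nx.community.modularity(g, list(groups.values()), weight="weight")
        if len(groups) > 1
        else 0.0
    )
    return CommunityPartition(
        colony_id=net.colony_id,
        membership=membership,
        modularity=float(mod),
        seed=seed,
        method=method,
    )


def label_and_map(
    partition: CommunityPartition,
    colony_stats: Sequence[SiteStats],
    site_tests: pd.DataFrame | None = None,
) -> tuple[CommunityPartition, pd.DataFrame]:
    """Label communities relative to the queen and build space-use maps.

    The community containing the queen becomes "nurse", all others "other".
    The returned map has one row per (community, site) with the mean visit
    count over community members and, when site tests are supplied, the
    consensus count: the number of members for which the site is classified
    attracted (by visit count).
    """
    stats_by_ant = {s.ant_id: s for s in colony_stats}
    queens = [s.ant_id for s in colony_stats if s.caste == "queen"]
    if partition.partitioned:
        if queens:
            nurse_comm = partition.membership[queens[0]]
            partition.labels = {
                c: ("nurse" if c == nurse_comm else "other")
                for c in set(partition.membership.values())
            }
        else:
            warnings.warn(
                f"colony {partition.colony_id}: no queen; labelling communities "
                "by index",
                stacklevel=2,
            )
            partition.labels = {
                c: f"community_{c}" for c in set(partition.membership.values())
            }
    attracted: dict[tuple[str, int], int] = {}
    if site_tests is not None:
        sub = site_tests[
            (site_tests["metric"] == "n")
            & (site_tests["classification"] == "attracted")
        ]
        for _, row in sub.iterrows():
            attracted[(row["ant"], int(row["site"]))] = 1
    rows = []
    groups: dict[int, list[str]] = {}
    for a, c in partition.membership.items():
        groups.setdefault(c, []).append(a)
    for comm, members in sorted(groups.items()):
        counts: dict[int, list[float]] = {}
        consensus: dict[int, int] = {}
        for a in members:
            if a not in stats_by_ant:
                continue
            for site, n in stats_by_ant[a].visit_counts.items():
                counts.setdefault(int(site), []).append(float(n))
                consensus[int(site)] = consensus.get(int(site), 0) + attracted.get(
                    (a, int(site)), 0
                )
        for site in sorted(counts):
            rows.append(
                {
                    "colony": partition.colony_id,
                    "community": comm,
                    "label": partition.labels.get(comm, "unpartitioned")
                    if partition.partitioned
                    else "unpartitioned",
                    "site": site,
                    "mean_visits": float(np.mean(counts[site])),
                    "consensus_count": consensus[site],
                }
            )
    return partition, pd.DataFrame(
        rows,
        columns=[
            "colony",
            "community",
            "label",
            "site",
            "mean_visits",
            "consensus_count",
        ],
    )


def write_graphml(
    net: OverlapNetwork, partition: CommunityPartition | None, path
) -> None:
    """GraphML export with caste/community/strength vertex attributes."""
    g = net.graph.copy()
    for a in g.nodes:
        if partition is not None:
            g.nodes[a]["community"] = int(partition.membership.get(a, -1))
            g.nodes[a]["community_label"] = partition.label_of(a)
    nx.write_graphml(g, path)
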