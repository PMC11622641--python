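"""Specificity co-dependency networks and their structural analysis.

From a species x site specificity matrix (one cohort, species with S > 0 at
every site) two signed correlation networks are built with Spearman's rho
and FDR edge selection:

* SSN — species specificity network: nodes are species, correlated across
  sites (co-dependency of specialisation profiles);
* SHN — site heterogeneity network: nodes are sites, correlated across
  species (similarity of sites' specificity signatures; built from the
  transposed matrix).

Annotations follow the conventions of ecological co-occurrence network
analysis: P/N ratio (positive over negative edge counts), degree hubs,
modularity clusters on |rho|, and a discrete core/periphery partition fit
by correlating the adjacency with the ideal pattern matrix (core-core
blocks dense, periphery-periphery blocks empty, core-periphery ties free)
and optimised by seeded greedy label swaps with restarts.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .landscape import OTUTable, ValidationError
from .specificity import specificity_from_groups

logger = logging.getLogger(__name__)

__all__ = [
    "SpecNetwork",
    "build_specificity_matrix",
    "correlation_network",
    "core_periphery",
    "core_periphery_score",
    "detect_clusters",
    "write_edge_list",
    "write_graphml",
]


@dataclass
class SpecNetwork:
    """Signed, weighted, undirected correlation network with annotations."""

    graph: nx.Graph
    mode: str  # "SSN" or "SHN"
    alpha: float
    n_observations: int
    pn_ratio: float | None = None  # None when no negative edges
    hubs: list = field(default_factory=list)
    core_labels: dict = field(default_factory=dict)
    core_fit: float | None = None
    clusters: list = field(default_factory=list)  # list of (node set, strength)

    @property
    def n_positive(self) -> int:
        return sum(1 for _, _, d in self.graph.edges(data=True) if d["sign"] > 0)

    @property
    def n_negative(self) -> int:
        return sum(1 for _, _, d in self.graph.edges(data=True) if d["sign"] < 0)

    def summary(self) -> dict:
        return {
            "mode": self.mode,
            "alpha": self.alpha,
            "n_nodes": self.graph.number_of_nodes(),
            "n_edges": self.graph.number_of_edges(),
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "pn_ratio": self.pn_ratio,
            "hubs": list(self.hubs),
            "core_fit": self.core_fit,
            "n_core": sum(1 for v in self.core_labels.values() if v == "core"),
        }


def build_specificity_matrix(
    table: OTUTable,
    meta: pd.DataFrame,
    habitat: str,
    sites: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Species x site specificity matrix for one cohort.

    Each body site is treated as a habitat of a multi-site landscape for the
    cohort, so a species' abundance shares compete across sites.  Only
    species with S > 0 at every site are retained (the inclusion rule for
    network analysis).  Needs >= 3 sites; below 5 the downstream
    correlations rest on very few paired observations and a warning is
    emitted.
    """
    cohort = meta[meta["habitat"] == habitat]
    if cohort.empty:
        raise LookupError(f"no samples with habitat {habitat!r}")
    if sites is None:
        sites = sorted(cohort["site"].unique())
    if len(sites) < 3:
        raise ValidationError("need >= 3 sites for a specificity matrix")
    if len(sites) < 5:
        warnings.warn(
            f"only {len(sites)} sites: correlations will have very low power",
            stacklevel=2,
        )
    col = {s: j for j, s in enumerate(table.sample_ids)}
    groups = {}
    for site in sites:
        ids = [
            s
            for s in cohort.loc[cohort["site"] == site, "sample_id"]
            if s in col
        ]
        if not ids:
            raise LookupError(f"no {habitat!r} samples at site {site!r}")
        groups[site] = np.array([col[s] for s in ids])
    used = np.concatenate(list(groups.values()))
    sub = OTUTable(
        list(table.species_ids),
        [table.sample_ids[i] for i in used],
        table.counts[:, used],
    )
    remap = {}
    start = 0
    for site, idx in groups.items():
        remap[site] = np.arange(start, start + idx.size)
        start += idx.size
    spec = specificity_from_groups(sub.counts, remap, sub.species_ids)
    matrix = spec.S.loc[(spec.S > 0).all(axis=1)]
    if matrix.empty:
        raise ValidationError("no species has positive specificity at all sites")
    logger.info(
        "specificity matrix for %s: %d species x %d sites",
        habitat, matrix.shape[0], matrix.shape[1],
    )
    return matrix


def correlation_network(
    matrix: pd.DataFrame, mode: str = "SSN", alpha: float = 0.01
) -> SpecNetwork:
    """Spearman correlation network with BH-FDR edge selection.

    Nodes are the matrix rows for SSN and its columns for SHN (the two modes
    correlate mutually transposed tables).  Edges are kept where the
    BH-adjusted Spearman p-value is below ``alpha``; edge sign is the sign
    of rho.  Pairs with an undefined rho (constant profile) are skipped with
    a log entry.
    """
    if mode == "SHN":
        matrix = matrix.T
    elif mode != "SSN":
        raise ValueError(f"unknown mode: {mode!r}")
    nodes = list(matrix.index)
    if len(nodes) < 2:
        raise ValidationError("need >= 2 nodes to correlate")
    n_obs = matrix.shape[1]
    if n_obs < 5:
        warnings.warn(
            f"only {n_obs} paired observations per correlation", stacklevel=2
        )
    values = matrix.to_numpy()
    pairs: list[tuple[int, int]] = []
    rhos: list[float] = []
    ps: list[float] = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            rho, p = stats.spearmanr(values[i], values[j])
            if not np.isfinite(rho) or not np.isfinite(p):
                logger.info(
                    "skipping pair (%s, %s): undefined correlation",
                    nodes[i], nodes[j],
                )
                continue
            pairs.append((i, j))
            rhos.append(float(rho))
            ps.append(float(p))
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    if pairs:
        _, qvals, _, _ = multipletests(ps, method="fdr_bh")
        for (i, j), rho, p, q in zip(pairs, rhos, ps, qvals):
            if q < alpha and rho != 0:
                graph.add_edge(
                    nodes[i],
                    nodes[j],
                    rho=rho,
                    p=p,
                    q=float(q),
                    sign=1 if rho > 0 else -1,
                    weight=abs(rho),
                )
    net = SpecNetwork(graph=graph, mode=mode, alpha=alpha, n_observations=n_obs)
    n_neg = net.n_negative
    net.pn_ratio = net.n_positive / n_neg if n_neg else None
    degrees = dict(graph.degree())
    max_deg = max(degrees.values(), default=0)
    net.hubs = (
        [v for v, d in degrees.items() if d == max_deg] if max_deg > 0 else []
    )
    return net


def core_periphery_score(
    graph: nx.Graph, core: set, nodes: Sequence | None = None
) -> float:
    """Fit of a core/periphery labeling against the ideal pattern matrix.

    The score is the Pearson correlation between the |weight| adjacency
    (scaled to [0, 1]) and the pattern (core-core pairs = 1,
    periphery-periphery pairs = 0) over those pairs; core-periphery pairs
    are free and excluded.  When either vector is constant the correlation
    degenerates and the score falls back to one minus the mean absolute
    mismatch, which ranks perfect agreement highest.
    """
    if nodes is None:
        nodes = list(graph.nodes)
    if not nodes:
        raise ValidationError("empty network")
    wmax = max(
        (abs(d.get("weight", 1.0)) for _, _, d in graph.edges(data=True)),
        default=1.0,
    )
    avec: list[float] = []
    pvec: list[float] = []
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            u_core, v_core = u in core, v in core
            if u_core != v_core:
                continue
            w = graph[u][v].get("weight", 1.0) / wmax if graph.has_edge(u, v) else 0.0
            avec.append(abs(w))
            pvec.append(1.0 if u_core else 0.0)
    if not avec:
        return 0.0
    a = np.asarray(avec)
    p = np.asarray(pvec)
    if a.std() == 0 or p.std() == 0:
        return float(1.0 - np.abs(a - p).mean())
    return float(np.corrcoef(a, p)[0, 1])


def _greedy_core(
    graph: nx.Graph,
    nodes: list,
    rng: np.random.Generator,
    restarts: int,
) -> set:
    best_core: set = set()
    best_score = -np.inf
    for r in range(restarts):
        if r == 0:  # degree-informed start: top half by degree
            order = sorted(nodes, key=lambda v: -graph.degree(v))
            core = set(order[: max(1, len(nodes) // 2)])
        else:
            mask = rng.random(len(nodes)) < 0.5
            core = {v for v, keep in zip(nodes, mask) if keep}
        score = core_periphery_score(graph, core, nodes)
        improved = True
        while improved:
            improved = False
            for v in rng.permutation(len(nodes)):
                node = nodes[int(v)]
                trial = set(core)
                if node in trial:
                    trial.discard(node)
                else:
                    trial.add(node)
                s = core_periphery_score(graph, trial, nodes)
                if s > score + 1e-12:
                    core, score = trial, s
                    improved = True
        if score > best_score:
            best_core, best_score = core, score
    return best_core


def core_periphery(
    network: SpecNetwork, seed: int | None = 0, restarts: int = 10
) -> tuple[dict, float]:
    """Discrete core/periphery assignment with a pattern-correlation fit.

    Each connected component with >= 3 nodes is optimised separately by
    seeded greedy label-swap hill climbing with restarts; smaller components
    are periphery by convention.  The all-core and all-periphery labelings
    are always evaluated as candidates, with ties broken toward all-core.
    Returns ``(labels, fit)`` where fit is the score of the final labeling
    over the whole graph; labels are also written onto the network.
    """
    graph = network.graph
    if graph.number_of_nodes() == 0:
        raise ValidationError("empty network")
    rng = np.random.default_rng(seed)
    core: set = set()
    for comp in nx.connected_components(graph):
        comp_nodes = sorted(comp, key=str)
        if len(comp_nodes) < 3:
            continue
        sub = graph.subgraph(comp_nodes)
        cand = _greedy_core(sub, comp_nodes, rng, restarts)
        options = [set(comp_nodes), cand, set()]  # prefer all-core on ties
        scores = [core_periphery_score(sub, c, comp_nodes) for c in options]
        core |= options[int(np.argmax(scores))]
    labels = {
        v: ("core" if v in core else "periphery") for v in graph.nodes
    }
    fit = core_periphery_score(graph, core)
    network.core_labels = labels
    network.core_fit = fit
    return labels, fit


def detect_clusters(
    network: SpecNetwork, seed: int | None = 0
) -> list[tuple[set, float]]:
    """Modularity communities on |rho| weights, ranked by mean intra-cluster
    |weight| (strength, 0 for edgeless clusters), strongest first.

    The sign composition inside each cluster is reported on the network
    nodes (``cluster`` attribute) rather than enforced.
    """
    graph = network.graph
    if graph.number_of_edges() < 1:
        raise ValidationError("need >= 1 edge to cluster")
    communities = nx.community.louvain_communities(
        graph, weight="weight", seed=seed
    )
    ranked = []
    for comm in communities:
        sub = graph.subgraph(comm)
        weights = [abs(d.get("weight", 1.0)) for _, _, d in sub.edges(data=True)]
        strength = float(np.mean(weights)) if weights else 0.0
        ranked.append((set(comm), strength))
    ranked.sort(key=lambda cs: (-cs[1], -len(cs[0])))
    for rank, (comm, _) in enumerate(ranked):
        for v in comm:
            graph.nodes[v]["cluster"] = rank
    network.clusters = ranked
    return ranked


def write_edge_list(network: SpecNetwork, path, provenance: str | None = None) -> None:
    rows = [
        {
            "node1": u,
            "node2": v,
            "rho": d["rho"],
            "p": d["p"],
            "q": d["q"],
            "sign": d["sign"],
        }
        for u, v, d in network.graph.edges(data=True)
    ]
    frame = pd.DataFrame(rows, columns=["node1", "node2", "rho", "p", "q", "sign"])
    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        frame.to_csv(fh, sep="\t", index=False)


def write_graphml(network: SpecNetwork, path) -> None:
    graph = network.graph.copy()
    for v in graph.nodes:
        graph.nodes[v]["core_periphery"] = network.core_labels.get(v, "")
        graph.nodes[v]["hub"] = v in network.hubs
    nx.write_graphml(graph, path)


def write_summary(network: SpecNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(network.summary(), fh, indent=2)
        fh.write("\n")
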