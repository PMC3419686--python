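"""Co-occurrence and taxon-trait correlation networks with Louvain modules.

Two network stages are supported:

* genus co-occurrence networks: Spearman rank correlations between
  relative-abundance vectors, edges kept at p < 0.001 (strict, configurable);
* integrated taxon-trait networks: Spearman cross-correlations between taxa
  and numeric clinical traits, edges kept at p <= 0.005, optionally augmented
  with the significant taxon-taxon edges.

Both are partitioned with a two-phase Louvain modularity optimizer written
here (local moving + graph aggregation, seeded visit order, Newman-Girvan
modularity on the unweighted simple graph).  Signed correlation coefficients
stay on the edges as attributes for reporting; modularity treats the graph
as unweighted because modularity with negative weights is not well defined.

No multiple-testing correction is applied by default (raw p-value
thresholds); a Benjamini-Hochberg option is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .abundance import CountTable, UNASSIGNED, relative_abundance
from .exceptions import AlignmentError, GutnetError, UndefinedStatisticError

__all__ = [
    "CorrelationNetwork",
    "ModulePartition",
    "spearman",
    "correlation_matrix",
    "build_network",
    "louvain",
    "modularity",
    "dominant_subnetwork",
    "trait_network",
    "filter_taxa",
]


def spearman(
    x: Sequence[float], y: Sequence[float], method: str = "t"
) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    ``method='t'`` uses the t approximation t = rho*sqrt((n-2)/(1-rho^2)) on
    n-2 df (accurate for the cohort sizes this pipeline targets);
    ``method='permutation'`` uses 10,000 random permutations (small n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise AlignmentError("sequences have different lengths")
    n = len(x)
    if n < 4:
        raise GutnetError("need at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("constant input: correlation undefined")
    if method == "t":
        rho, p = stats.spearmanr(x, y)
        if abs(rho) >= 1.0 - 1e-12:  # perfect monotone association
            return float(np.sign(rho)), 0.0
        return float(rho), float(p)
    if method == "permutation":
        rng = np.random.default_rng(0)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = np.corrcoef(rx, ry)[0, 1]
        n_perm = 10_000
        perms = np.empty(n_perm)
        for i in range(n_perm):
            perms[i] = np.corrcoef(rx, rng.permutation(ry))[0, 1]
        p = (1 + np.sum(np.abs(perms) >= abs(obs) - 1e-12)) / (1 + n_perm)
        return float(obs), float(p)
    raise ValueError(f"unknown method {method!r}")


def _rank_rows(mat: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, mat)


def _p_from_rho(rho: np.ndarray, n: int | np.ndarray) -> np.ndarray:
    """Two-sided p from the t approximation; |rho|=1 maps to p=0."""
    rho = np.clip(np.asarray(rho, dtype=float), -1.0, 1.0)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return p


def correlation_matrix(
    profiles: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho and p between rows of a features-by-samples frame.

    Rows are features (taxa), columns are samples.  Diagonal: rho=1, p=0.
    """
    if profiles.shape[1] < 4:
        raise GutnetError("need at least 4 samples")
    mat = profiles.to_numpy(dtype=float)
    const = np.all(mat == mat[:, [0]], axis=1)
    if const.any():
        bad = list(profiles.index[const])
        raise UndefinedStatisticError(
            f"constant feature(s), correlation undefined: {bad[:5]}"
        )
    ranks = _rank_rows(mat)
    rho = np.corrcoef(ranks)
    n = profiles.shape[1]
    p = _p_from_rho(rho, n)
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    idx = profiles.index
    return (
        pd.DataFrame(rho, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
    )


class CorrelationNetwork:
    """Simple graph of taxa and/or traits with signed Spearman-weighted edges.

    Wraps a :class:`networkx.Graph`; edges carry ``rho``, ``p``, ``sign``
    ("positive"/"inverse") and ``n`` (observations used); taxon nodes carry
    ``mean_abundance`` when available.
    """

    def __init__(self, graph: nx.Graph, alpha: float, rule: str):
        self.graph = graph
        self.alpha = alpha
        self.rule = rule

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges_frame(self, partition: "ModulePartition | None" = None) -> pd.DataFrame:
        rows = []
        for a, b, attrs in self.graph.edges(data=True):
            row = {
                "node_a": a,
                "node_b": b,
                "rho": attrs["rho"],
                "p": attrs["p"],
                "sign": attrs["sign"],
                "n": attrs.get("n"),
            }
            if partition is not None:
                row["module_a"] = partition.modules[a]
                row["module_b"] = partition.modules[b]
            rows.append(row)
        cols = ["node_a", "node_b", "rho", "p", "sign", "n"]
        if partition is not None:
            cols += ["module_a", "module_b"]
        frame = pd.DataFrame(rows, columns=cols)
        return frame.sort_values(["node_a", "node_b"]).reset_index(drop=True)

    def nodes_frame(self, partition: "ModulePartition | None" = None) -> pd.DataFrame:
        rows = []
        for node, attrs in self.graph.nodes(data=True):
            row = {
                "node": node,
                "kind": attrs.get("kind", "taxon"),
                "mean_abundance": attrs.get("mean_abundance", np.nan),
                "degree": self.graph.degree(node),
            }
            if partition is not None:
                row["module"] = partition.modules[node]
            rows.append(row)
        return pd.DataFrame(rows).sort_values("node").reset_index(drop=True)

    def write_graphml(self, path: str | Path) -> None:
        clean = nx.Graph()
        for node, attrs in self.graph.nodes(data=True):
            clean.add_node(
                node,
                **{k: v for k, v in attrs.items() if v is not None
                   and not (isinstance(v, float) and np.isnan(v))},
            )
        for a, b, attrs in self.graph.edges(data=True):
            clean.add_edge(
                a, b, **{k: v for k, v in attrs.items() if v is not None}
            )
        nx.write_graphml(clean, path)


def build_network(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    alpha: float,
    rule: str = "strict-less",
    node_attrs: Mapping[str, Mapping[str, object]] | None = None,
) -> CorrelationNetwork:
    """Threshold a correlation matrix into a simple graph.

    ``rule='strict-less'`` keeps edges with p < alpha (the taxon-taxon
    convention); ``rule='less-equal'`` keeps p <= alpha (taxon-trait).
    Every feature becomes a node, connected or not.
    """
    if not 0 < alpha < 1:
        raise GutnetError("alpha must be in (0, 1)")
    if rule not in ("strict-less", "less-equal"):
        raise GutnetError(f"unknown rule {rule!r}")
    if list(rho.index) != list(p.index) or list(rho.columns) != list(p.columns):
        raise AlignmentError("rho and p matrices are not aligned")
    graph = nx.Graph()
    for node in rho.index:
        attrs = dict(node_attrs.get(node, {})) if node_attrs else {}
        attrs.setdefault("kind", "taxon")
        graph.add_node(node, **attrs)
    names = list(rho.index)
    pv = p.to_numpy()
    rv = rho.to_numpy()
    n_obs = rho.shape[1]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            keep = pv[i, j] < alpha if rule == "strict-less" else pv[i, j] <= alpha
            if keep:
                graph.add_edge(
                    names[i],
                    names[j],
                    rho=float(rv[i, j]),
                    p=float(pv[i, j]),
                    sign="positive" if rv[i, j] > 0 else "inverse",
                    n=None,
                )
    return CorrelationNetwork(graph, alpha, rule)


@dataclass
class ModulePartition:
    """Node -> module id with the Newman-Girvan modularity of the partition."""

    modules: dict[str, int]
    q: float


def modularity(
    net: CorrelationNetwork | nx.Graph, partition: Mapping[str, int]
) -> float:
    """Newman-Girvan modularity Q = sum_c [e_c/m - (d_c/2m)^2], unweighted."""
    graph = net.graph if isinstance(net, CorrelationNetwork) else net
    unknown = [n for n in graph.nodes if n not in partition]
    if unknown:
        raise GutnetError(f"partition misses node(s): {unknown[:5]}")
    extra = [n for n in partition if n not in graph.nodes]
    if extra:
        raise GutnetError(f"partition has unknown node(s): {extra[:5]}")
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    e_c: dict[int, int] = {}
    d_c: dict[int, int] = {}
    for node in graph.nodes:
        c = partition[node]
        d_c[c] = d_c.get(c, 0) + graph.degree(node)
    for a, b in graph.edges:
        if partition[a] == partition[b]:
            c = partition[a]
            e_c[c] = e_c.get(c, 0) + 1
    q = 0.0
    for c, deg in d_c.items():
        q += e_c.get(c, 0) / m - (deg / (2 * m)) ** 2
    return q


def louvain(
    net: CorrelationNetwork | nx.Graph,
    seed: int = 0,
    resolution: float = 1.0,
    n_restarts: int = 10,
) -> ModulePartition:
    """Two-phase Louvain modularity optimization (seeded, deterministic).

    Phase 1 repeatedly moves each node (in a seed-shuffled order) to the
    neighbouring community with the largest positive modularity gain; phase 2
    aggregates communities into super-nodes and repeats.  The greedy sweep is
    restarted ``n_restarts`` times with sub-seeded visit orders and the
    best-modularity partition is kept (single sweeps are prone to shallow
    local optima on small graphs).  The input graph is treated as unweighted;
    aggregated graphs carry the induced weights.  Isolated nodes (or an
    edgeless graph) each form their own module.
    """
    graph = net.graph if isinstance(net, CorrelationNetwork) else net
    if len(graph.nodes) == 0:
        raise GutnetError("empty graph")
    best: ModulePartition | None = None
    for sub in np.random.SeedSequence(seed).spawn(max(1, n_restarts)):
        part = _louvain_once(graph, np.random.default_rng(sub), resolution)
        if best is None or part.q > best.q:
            best = part
    return best


def _louvain_once(
    graph: nx.Graph, rng: np.random.Generator, resolution: float
) -> ModulePartition:
    nodes = list(graph.nodes)

    # adjacency with unit weights; node index space 0..n-1
    index = {node: i for i, node in enumerate(nodes)}
    adj: list[dict[int, float]] = [dict() for _ in nodes]
    for a, b in graph.edges:
        ia, ib = index[a], index[b]
        if ia == ib:
            continue
        adj[ia][ib] = adj[ia].get(ib, 0.0) + 1.0
        adj[ib][ia] = adj[ib].get(ia, 0.0) + 1.0
    two_m = sum(sum(neigh.values()) for neigh in adj)
    if two_m == 0:
        return ModulePartition({node: i + 1 for i, node in enumerate(nodes)}, 0.0)

    # mapping from original node index to current community through levels
    node_to_comm = list(range(len(nodes)))

    cur_adj = adj
    cur_self = [0.0] * len(nodes)  # self-loop weight per super-node
    while True:
        n = len(cur_adj)
        degree = [sum(cur_adj[i].values()) + 2 * cur_self[i] for i in range(n)]
        comm = list(range(n))
        comm_tot = degree[:]  # sum of degrees in community
        improved = False
        moved = True
        while moved:
            moved = False
            order = rng.permutation(n)
            for i in order:
                ci = comm[i]
                # weights from i to neighbouring communities
                links: dict[int, float] = {}
                for j, w in cur_adj[i].items():
                    links[comm[j]] = links.get(comm[j], 0.0) + w
                comm_tot[ci] -= degree[i]
                base = links.get(ci, 0.0)
                best_c, best_gain = ci, 0.0
                for c, w in sorted(links.items()):
                    gain = (w - base) - resolution * degree[i] * (
                        comm_tot[c] - comm_tot[ci]
                    ) / two_m
                    if gain > best_gain + 1e-12:
                        best_c, best_gain = c, gain
                comm_tot[best_c] += degree[i]
                if best_c != ci:
                    comm[i] = best_c
                    moved = True
                    improved = True
        if not improved:
            break
        # renumber communities densely and aggregate
        remap: dict[int, int] = {}
        for c in comm:
            if c not in remap:
                remap[c] = len(remap)
        comm = [remap[c] for c in comm]
        node_to_comm = [comm[c] for c in node_to_comm]
        n_new = len(remap)
        new_adj: list[dict[int, float]] = [dict() for _ in range(n_new)]
        new_self = [0.0] * n_new
        for i in range(n):
            new_self[comm[i]] += cur_self[i]
            for j, w in cur_adj[i].items():
                if i < j:
                    ci, cj = comm[i], comm[j]
                    if ci == cj:
                        new_self[ci] += w
                    else:
                        new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + w
                        new_adj[cj][ci] = new_adj[cj].get(ci, 0.0) + w
        cur_adj = new_adj
        cur_self = new_self
        if n_new == n:
            break

    # dense module ids in first-seen node order, 1-based
    remap2: dict[int, int] = {}
    modules: dict[str, int] = {}
    for node in nodes:
        c = node_to_comm[index[node]]
        if c not in remap2:
            remap2[c] = len(remap2) + 1
        modules[node] = remap2[c]
    q = modularity(graph, modules)
    return ModulePartition(modules, q)


def dominant_subnetwork(net: CorrelationNetwork, anchor: str) -> CorrelationNetwork:
    """Induced subgraph on an anchor genus and its direct neighbours.

    Keeps every edge of the parent network between retained nodes (anchor
    edges plus neighbour-neighbour edges).
    """
    if anchor not in net.graph:
        raise GutnetError(f"anchor {anchor!r} not in network")
    keep = {anchor} | set(net.graph.neighbors(anchor))
    sub = net.graph.subgraph(keep).copy()
    return CorrelationNetwork(sub, net.alpha, net.rule)


def filter_taxa(
    table: CountTable,
    min_prevalence: float = 0.10,
    detection_min: int = 1,
    exclude_unassigned: bool = True,
) -> pd.DataFrame:
    """Relative abundances of taxa passing a prevalence floor.

    Removes near-absent taxa (constant-vector hazards for rank correlation)
    before network construction.
    """
    rel = relative_abundance(table)
    prev = (table.data >= detection_min).sum(axis=1) / table.n_samples
    keep = prev[prev >= min_prevalence].index
    if exclude_unassigned:
        keep = [t for t in keep if t != UNASSIGNED]
    return rel.loc[keep]


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def trait_network(
    taxa_profiles: pd.DataFrame,
    trait_table: pd.DataFrame,
    alpha: float = 0.005,
    include_taxon_taxon: bool = False,
    taxon_alpha: float = 0.001,
    bh_correct: bool = False,
) -> CorrelationNetwork:
    """Bipartite taxon-trait Spearman network at p <= alpha.

    ``taxa_profiles`` is taxa-by-samples relative abundance; ``trait_table``
    is samples-by-traits numeric.  Missing trait values are handled
    pairwise-complete, with the per-edge n recorded; candidate pairs with
    n < 4 complete cases are skipped with a warning.  With
    ``include_taxon_taxon`` the significant taxon-taxon edges (strict
    p < taxon_alpha) are added as well.
    """
    if not 0 < alpha < 1:
        raise GutnetError("alpha must be in (0, 1)")
    samples = list(taxa_profiles.columns)
    if not set(samples) <= set(trait_table.index):
        missing = sorted(set(samples) - set(trait_table.index))
        raise AlignmentError(f"samples missing from trait table: {missing[:5]}")
    traits = trait_table.loc[samples]
    graph = nx.Graph()
    mean_ab = taxa_profiles.mean(axis=1)
    for taxon in taxa_profiles.index:
        graph.add_node(taxon, kind="taxon", mean_abundance=float(mean_ab[taxon]))
    for trait in traits.columns:
        graph.add_node(trait, kind="trait")

    records = []  # (taxon, trait, rho, p, n)
    tp = taxa_profiles.to_numpy(dtype=float)
    for trait in traits.columns:
        tv = pd.to_numeric(traits[trait], errors="coerce").to_numpy(dtype=float)
        mask = ~np.isnan(tv)
        n = int(mask.sum())
        if n < 4:
            warnings.warn(
                f"trait {trait!r}: fewer than 4 complete cases; skipped",
                stacklevel=2,
            )
            continue
        rt = stats.rankdata(tv[mask])
        for k, taxon in enumerate(taxa_profiles.index):
            xv = tp[k, mask]
            if np.all(xv == xv[0]) or np.all(rt == rt[0]):
                continue
            rho = np.corrcoef(stats.rankdata(xv), rt)[0, 1]
            p = float(_p_from_rho(np.array([rho]), n)[0])
            records.append((taxon, trait, float(rho), p, n))
    if records:
        pvals = np.array([r[3] for r in records])
        padj = _bh_adjust(pvals) if bh_correct else pvals
        for (taxon, trait, rho, p, n), pa in zip(records, padj):
            if pa <= alpha:
                graph.add_edge(
                    taxon, trait, rho=rho, p=p,
                    sign="positive" if rho > 0 else "inverse", n=n,
                )
    if include_taxon_taxon and taxa_profiles.shape[0] >= 2:
        rho_tt, p_tt = correlation_matrix(taxa_profiles)
        names = list(taxa_profiles.index)
        pv = p_tt.to_numpy()
        rv = rho_tt.to_numpy()
        pkeep = _bh_adjust(pv[np.triu_indices(len(names), 1)]) if bh_correct else None
        idx = 0
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                p_use = pkeep[idx] if bh_correct else pv[i, j]
                idx += 1
                if p_use < taxon_alpha:
                    graph.add_edge(
                        names[i], names[j],
                        rho=float(rv[i, j]), p=float(pv[i, j]),
                        sign="positive" if rv[i, j] > 0 else "inverse",
                        n=taxa_profiles.shape[1],
                    )
    return CorrelationNetwork(graph, alpha, "less-equal")
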