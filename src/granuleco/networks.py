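"""Consensus co-occurrence networks, modules and their temporal dynamics.

An edge between two ASVs requires agreement of two correlation methods on
relative-abundance profiles across the time series: Spearman's rank
correlation and SparCC. Both absolute correlations must exceed a threshold
(default 0.6) and both BH-FDR corrected p-values must fall below alpha
(default 0.05); edges whose two correlations disagree in sign are dropped.
Modules (sub-communities) are found with the walktrap random-walk
algorithm; their temporal behaviour is summarized by module completeness
(fraction of member ASVs detected in a sample) and module abundance
(summed relative abundance). Per-time-point network properties come from
the subgraph induced on the ASVs present in that sample. The inter-kingdom
structure is a bipartite network of significant positive consensus
correlations between core ASVs (present in >75% of samples) of the two
kingdoms.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .sparcc import sparcc_correlations

__all__ = [
    "spearman_correlations",
    "bh_adjust",
    "correlation_qvalues",
    "ConsensusNetwork",
    "build_consensus_network",
    "consensus_network_from_table",
    "detect_modules",
    "module_dynamics",
    "per_sample_network_stats",
    "BipartiteNetwork",
    "build_bipartite_core_network",
]


def spearman_correlations(table_or_matrix) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Spearman rho and two-sided p (t approximation).

    Accepts a CountTable (uses row-closed relative abundances) or a plain
    samples x variables matrix. Pairs involving a constant column are
    recorded as missing (NaN).
    """
    x = (
        table_or_matrix.relative_abundance()
        if hasattr(table_or_matrix, "relative_abundance")
        else np.asarray(table_or_matrix, dtype=float)
    )
    n, p = x.shape
    if n < 5:
        raise ValueError("need at least 5 samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, pval = stats.spearmanr(x, axis=0)
    rho = np.atleast_2d(rho)
    pval = np.atleast_2d(pval)
    const = x.std(axis=0) == 0
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    pval[const, :] = np.nan
    pval[:, const] = np.nan
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(pval, 0.0)
    return rho, pval


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment of a p-value vector."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D vector")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return stats.false_discovery_control(p, method="bh")


def correlation_qvalues(pmat: np.ndarray) -> np.ndarray:
    """BH-adjust the upper triangle of a symmetric p-value matrix."""
    p = np.asarray(pmat, dtype=float)
    iu = np.triu_indices(p.shape[0], k=1)
    vals = p[iu]
    ok = np.isfinite(vals)
    q = np.full_like(vals, np.nan)
    if ok.any():
        q[ok] = bh_adjust(np.clip(vals[ok], 1e-300, 1.0))
    out = np.full_like(p, np.nan)
    out[iu] = q
    out.T[iu] = q
    np.fill_diagonal(out, 0.0)
    return out


@dataclass
class ConsensusNetwork:
    """Undirected simple graph of consensus co-occurrences.

    Nodes are ASV ids with ``kingdom``, ``abundance`` (mean relative
    abundance) and, after :func:`detect_modules`, ``module`` attributes.
    Edges carry ``rho``, ``r_sparcc``, ``q_rho``, ``q_sparcc``, ``sign``
    and ``weight`` = mean(|rho|, |r_sparcc|).
    """

    graph: nx.Graph
    kingdom: str = "prokaryote"
    modules: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges_table(self) -> pd.DataFrame:
        rows = [
            {"node1": u, "node2": v, **d} for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(
            rows, columns=["node1", "node2", "rho", "r_sparcc", "q_rho", "q_sparcc", "sign", "weight"]
        )

    def nodes_table(self) -> pd.DataFrame:
        rows = [{"node": n, **d} for n, d in self.graph.nodes(data=True)]
        return pd.DataFrame(rows)


def build_consensus_network(
    asv_ids,
    rho: np.ndarray,
    r_sparcc: np.ndarray,
    q_rho: np.ndarray,
    q_sparcc: np.ndarray,
    kingdom: str = "prokaryote",
    corr_threshold: float = 0.6,
    alpha: float = 0.05,
    abundance=None,
) -> ConsensusNetwork:
    """Apply the dual-method consensus rule to correlation matrices.

    Edge iff |rho| > threshold AND |r_sparcc| > threshold AND both FDR
    q-values < alpha; the edge sign is the sign of rho and must agree with
    the SparCC sign (disagreements are dropped with a warning).
    """
    p = len(asv_ids)
    for m in (rho, r_sparcc, q_rho, q_sparcc):
        if np.shape(m) != (p, p):
            raise ValueError("matrices must be (n_asvs, n_asvs)")
    g = nx.Graph()
    for k, a in enumerate(asv_ids):
        g.add_node(
            a,
            kingdom=kingdom,
            abundance=float(abundance[k]) if abundance is not None else np.nan,
        )
    dropped = 0
    iu = zip(*np.triu_indices(p, k=1))
    for i, j in iu:
        if not (np.isfinite(rho[i, j]) and np.isfinite(r_sparcc[i, j])):
            continue
        if (
            abs(rho[i, j]) > corr_threshold
            and abs(r_sparcc[i, j]) > corr_threshold
            and q_rho[i, j] < alpha
            and q_sparcc[i, j] < alpha
        ):
            if np.sign(rho[i, j]) != np.sign(r_sparcc[i, j]):
                dropped += 1
                continue
            g.add_edge(
                asv_ids[i],
                asv_ids[j],
                rho=float(rho[i, j]),
                r_sparcc=float(r_sparcc[i, j]),
                q_rho=float(q_rho[i, j]),
                q_sparcc=float(q_sparcc[i, j]),
                sign=int(np.sign(rho[i, j])),
                weight=float(0.5 * (abs(rho[i, j]) + abs(r_sparcc[i, j]))),
            )
    if dropped:
        warnings.warn(f"{dropped} candidate edges dropped for sign disagreement")
    return ConsensusNetwork(g, kingdom=kingdom)


def consensus_network_from_table(
    table,
    corr_threshold: float = 0.6,
    alpha: float = 0.05,
    seed: int | None = None,
    sparcc_kwargs: dict | None = None,
) -> ConsensusNetwork:
    """Full stack: Spearman + SparCC + FDR + consensus rule on one table."""
    rho, p_rho = spearman_correlations(table)
    r, p_r = sparcc_correlations(table.counts, seed=seed, **(sparcc_kwargs or {}))
    net = build_consensus_network(
        table.asv_ids,
        rho,
        r,
        correlation_qvalues(p_rho),
        correlation_qvalues(p_r),
        kingdom=table.kingdom,
        corr_threshold=corr_threshold,
        alpha=alpha,
        abundance=table.relative_abundance().mean(axis=0),
    )
    return net


def _walktrap_membership(g: nx.Graph, steps: int) -> dict:
    """Walktrap community membership on absolute edge weights."""
    nodes = list(g.nodes)
    index = {n: k for k, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges]
    weights = [abs(d.get("weight", 1.0)) for _, _, d in g.edges(data=True)]
    h = ig.Graph(n=len(nodes), edges=edges)
    dend = h.community_walktrap(weights=weights if edges else None, steps=steps)
    clustering = dend.as_clustering()  # cut maximizing modularity
    return {n: clustering.membership[index[n]] for n in nodes}


def detect_modules(
    network: ConsensusNetwork, steps: int = 4, table=None
) -> dict:
    """Walktrap modules of a consensus network.

    Communities are detected on absolute edge weights with the cut that
    maximizes weighted modularity; isolated nodes get their own singleton
    labels. Modules are relabelled 1..k ordered by summed mean node
    abundance (module 1 = most abundant; falls back to size when no
    abundances are available), and the labels are stored on the node
    attribute ``module``.
    """
    g = network.graph
    if g.number_of_edges() == 0:
        warnings.warn("network has no edges: every node is its own module")
        raw = {n: k for k, n in enumerate(g.nodes)}
    else:
        raw = _walktrap_membership(g, steps)
    if table is not None:
        mean_ab = dict(
            zip(table.asv_ids, table.relative_abundance().mean(axis=0))
        )
    else:
        mean_ab = {n: d.get("abundance", np.nan) for n, d in g.nodes(data=True)}
    score = {}
    for n, m in raw.items():
        v = mean_ab.get(n, np.nan)
        score[m] = score.get(m, 0.0) + (v if np.isfinite(v) else 1.0 / max(len(raw), 1))
    order = sorted(score, key=lambda m: (-score[m], m))
    relabel = {m: k + 1 for k, m in enumerate(order)}
    labels = {n: relabel[m] for n, m in raw.items()}
    nx.set_node_attributes(g, labels, "module")
    network.modules = labels
    return labels


def module_dynamics(network: ConsensusNetwork, table) -> pd.DataFrame:
    """Per-module, per-sample completeness and abundance.

    completeness(M, t) = fraction of M's nodes with count > 0 at t;
    abundance(M, t) = summed relative abundance of M's nodes at t.
    """
    if not network.modules:
        raise ValueError("run detect_modules first")
    missing = [n for n in network.graph.nodes if n not in set(table.asv_ids)]
    if missing:
        raise ValueError(f"network nodes absent from table: {missing[:5]}")
    col = {a: k for k, a in enumerate(table.asv_ids)}
    rel = table.relative_abundance()
    rows = []
    by_module: dict = {}
    for n, m in network.modules.items():
        by_module.setdefault(m, []).append(col[n])
    for m in sorted(by_module):
        idx = np.array(by_module[m])
        pres = (table.counts[:, idx] > 0).mean(axis=1)
        ab = rel[:, idx].sum(axis=1)
        for i, sid in enumerate(table.sample_ids):
            rows.append(
                {
                    "module": m,
                    "sample_id": sid,
                    "day": None if table.days is None else float(table.days[i]),
                    "completeness": float(pres[i]),
                    "abundance": float(ab[i]),
                }
            )
    return pd.DataFrame(rows)


def per_sample_network_stats(
    network: ConsensusNetwork, table, steps: int = 4
) -> pd.DataFrame:
    """Properties of each sample's induced subnetwork.

    For every sample the subgraph on present nodes (count > 0) is taken
    from the consensus network; edge density, global (triangle) clustering
    and the weighted modularity of a fresh walktrap run on the subgraph are
    recorded. Subgraphs with fewer than 2 nodes yield missing values.
    """
    col = {a: k for k, a in enumerate(table.asv_ids)}
    rows = []
    for i, sid in enumerate(table.sample_ids):
        present = [n for n in network.graph.nodes if table.counts[i, col[n]] > 0]
        rec = {
            "sample_id": sid,
            "day": None if table.days is None else float(table.days[i]),
            "n_nodes": len(present),
        }
        if len(present) < 2:
            rec.update(n_edges=np.nan, density=np.nan, clustering=np.nan, modularity=np.nan)
            rows.append(rec)
            continue
        sub = network.graph.subgraph(present)
        rec["n_edges"] = sub.number_of_edges()
        rec["density"] = nx.density(sub)
        rec["clustering"] = nx.transitivity(sub)
        if sub.number_of_edges() == 0:
            rec["modularity"] = np.nan
        else:
            membership = _walktrap_membership(sub, steps)
            groups: dict = {}
            for n, m in membership.items():
                groups.setdefault(m, set()).add(n)
            rec["modularity"] = nx.community.modularity(
                sub, list(groups.values()), weight="weight"
            )
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class BipartiteNetwork:
    """Positive consensus correlations between core ASVs of two kingdoms."""

    graph: nx.Graph
    prok_core: list
    euk_core: list
    module_pair_counts: pd.DataFrame

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges_table(self) -> pd.DataFrame:
        rows = [
            {"prok": u if self.graph.nodes[u]["kingdom"] == "prokaryote" else v,
             "euk": v if self.graph.nodes[v]["kingdom"] == "eukaryote" else u,
             **d}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows)


def build_bipartite_core_network(
    prok_table,
    euk_table,
    core_prevalence: float = 0.75,
    corr_threshold: float = 0.6,
    alpha: float = 0.05,
    seed: int | None = None,
    sparcc_kwargs: dict | None = None,
    prok_modules: dict | None = None,
    euk_modules: dict | None = None,
) -> BipartiteNetwork:
    """Inter-kingdom bipartite network of the core community.

    Each kingdom is restricted to its core ASVs (present in more than
    ``core_prevalence`` of samples). Cross-kingdom Spearman correlations are
    computed on the per-kingdom closed compositions; cross-kingdom SparCC on
    the concatenated count table with a kingdom-blocked Dirichlet draw (each
    kingdom's fractions closed separately). Only positive consensus edges
    are kept, FDR-corrected over the cross-kingdom pair pool; within-kingdom
    pairs are excluded by construction. Node module labels can be supplied
    from the within-kingdom consensus networks.
    """
    if prok_table.sample_ids != euk_table.sample_ids:
        raise ValueError("tables must share an identical sample set and order")
    cores = []
    for tb in (prok_table, euk_table):
        keep = tb.presence().mean(axis=0) > core_prevalence
        if not keep.any():
            raise ValueError(f"empty core for {tb.kingdom} at prevalence {core_prevalence}")
        cores.append(
            type(tb)(
                tb.sample_ids,
                [a for a, k in zip(tb.asv_ids, keep) if k],
                tb.counts[:, keep],
                kingdom=tb.kingdom,
                days=tb.days,
            )
        )
    pk, ek = cores
    npk, nek = pk.n_asvs, ek.n_asvs
    # Spearman on per-kingdom closed compositions
    x = np.hstack([pk.relative_abundance(), ek.relative_abundance()])
    rho, p_rho = spearman_correlations(x)
    # SparCC on the concatenated counts with kingdom-blocked Dirichlet
    # closure: the two kingdoms were sequenced as separate compositions, so
    # each block's fractions are closed separately before the log-ratio step.
    counts = np.hstack([pk.counts, ek.counts])
    blocks = (slice(0, npk), slice(npk, npk + nek))
    r, p_r = sparcc_correlations(
        counts, seed=seed, blocks=blocks, **(sparcc_kwargs or {})
    )
    cross = np.zeros((npk + nek, npk + nek), dtype=bool)
    cross[:npk, npk:] = True
    # FDR over the cross-kingdom pool only
    def _cross_q(pm):
        q = np.full_like(pm, np.nan)
        vals = pm[cross]
        ok = np.isfinite(vals)
        adj = np.full_like(vals, np.nan)
        if ok.any():
            adj[ok] = bh_adjust(np.clip(vals[ok], 1e-300, 1.0))
        q[cross] = adj
        return q

    q_rho, q_r = _cross_q(p_rho), _cross_q(p_r)
    ids = pk.asv_ids + ek.asv_ids
    g = nx.Graph()
    for a in pk.asv_ids:
        g.add_node(a, kingdom="prokaryote", module=(prok_modules or {}).get(a))
    for a in ek.asv_ids:
        g.add_node(a, kingdom="eukaryote", module=(euk_modules or {}).get(a))
    for i in range(npk):
        for j in range(npk, npk + nek):
            if not (np.isfinite(rho[i, j]) and np.isfinite(r[i, j])):
                continue
            if (
                rho[i, j] > corr_threshold
                and r[i, j] > corr_threshold
                and q_rho[i, j] < alpha
                and q_r[i, j] < alpha
            ):
                g.add_edge(
                    ids[i],
                    ids[j],
                    rho=float(rho[i, j]),
                    r_sparcc=float(r[i, j]),
                    q_rho=float(q_rho[i, j]),
                    q_sparcc=float(q_r[i, j]),
                    sign=1,
                    weight=float(0.5 * (rho[i, j] + r[i, j])),
                )
    pairs: dict = {}
    for u, v in g.edges:
        mu = g.nodes[u].get("module")
        mv = g.nodes[v].get("module")
        if g.nodes[u]["kingdom"] == "eukaryote":
            mu, mv = mv, mu
        pairs[(mu, mv)] = pairs.get((mu, mv), 0) + 1
    pair_df = pd.DataFrame(
        [
            {"prok_module": k[0], "euk_module": k[1], "n_edges": v}
            for k, v in sorted(pairs.items(), key=str)
        ],
        columns=["prok_module", "euk_module", "n_edges"],
    )
    return BipartiteNetwork(g, pk.asv_ids, ek.asv_ids, pair_df)
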