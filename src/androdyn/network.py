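"""PPI-network integration: hubs, neighborhoods, cluster-pair statistics,
the molecular-type interaction map, and C->D->E cascade enumeration.

A cascade is an ordered protein triple (c, d, e) with cluster labels C, D, E
and PPI edges {c,d} and {d,e}; the published table restricts the terminal
member to transcription regulators, which is the default here (switchable).
Cluster-pair over-representation uses an edge-universe hypergeometric: among
all unordered node pairs (M) of which K are observed edges, how surprising
is seeing x edges among the n pairs spanning the two clusters.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULT_ROW_MAP
from .errors import AndrodynError, ParameterError
from .fcm import CLUSTER_RANK, ClusterAssignment
from .io import AnnotationTable, normalize_symbol

log = logging.getLogger("androdyn")

CASCADE_ROWS = ("plasma membrane", "cytoplasm", "nucleus")
CASCADE_COLUMNS = ("C", "D", "E")


def restrict_network(network: nx.Graph, assignment: ClusterAssignment,
                     annotations: AnnotationTable | None = None) -> nx.Graph:
    """Induced subgraph on labeled proteins, with cluster (and, when
    available, compartment/type) node attributes attached."""
    nodes = [n for n in network.nodes if n in assignment.labels.index]
    sub = network.subgraph(nodes).copy()
    if not nodes:
        log.warning("restrict_network: no labeled protein present in network")
    nx.set_node_attributes(
        sub, {n: assignment.labels[n] for n in sub.nodes}, "cluster")
    if annotations is not None:
        tab = annotations.table
        for col in ("compartment", "molecular_type"):
            nx.set_node_attributes(
                sub, {n: tab.at[n, col] for n in sub.nodes if n in tab.index},
                col)
    return sub


def hub_degrees(network: nx.Graph, top_n: int = 15,
                focus: tuple[str, ...] = ()) -> pd.DataFrame:
    """Nodes ranked by degree (descending, ties by symbol).

    Returns the top ``top_n`` plus any named focus proteins present in the
    network regardless of rank.
    """
    deg = sorted(network.degree(), key=lambda kv: (-kv[1], kv[0]))
    table = pd.DataFrame(deg, columns=["protein", "degree"])
    table["rank"] = range(1, len(table) + 1)
    focus = {normalize_symbol(f) for f in focus}
    keep = (table["rank"] <= top_n) | table["protein"].isin(focus)
    return table[keep].reset_index(drop=True)


def ego_neighborhood(network: nx.Graph, focus: str = "AR",
                     radius: int = 2) -> nx.Graph:
    """Subgraph within graph distance ``radius`` of the focus protein."""
    focus = normalize_symbol(focus)
    if focus not in network:
        raise AndrodynError(f"focus protein {focus!r} absent from network")
    return nx.ego_graph(network, focus, radius=radius)


# ---------------------------------------------------------------------------
# Cluster-pair over-representation
# ---------------------------------------------------------------------------

@dataclass
class ClusterPairStats:
    """Per-pair edge counts, percentages and over-representation p-values.

    ``table`` has one row per unordered cluster pair (within-cluster pairs
    included): columns edges, pct_all (over all counted edges), pct_inter
    (over inter-cluster edges only), n_pairs, p, significant, and (when
    permutations were requested) p_rewire.
    """

    table: pd.DataFrame
    total_edges: int
    flagged: tuple[tuple[str, str], ...]


def cluster_pair_stats(network: nx.Graph, assignment: ClusterAssignment,
                       alpha: float = 0.05, permutations: int = 0,
                       seed: int = 0) -> ClusterPairStats:
    """Count PPIs between every pair of clusters and test over-representation.

    The hypergeometric universe is all unordered pairs among labeled nodes
    in the network (M), of which the observed edges are the draws (K); for a
    cluster pair, n is the number of node pairs spanning it and x the edges
    among them.  An optional degree-preserving rewiring null adds an
    empirical p-value column as a robustness check.  The ``flagged`` set
    applies a Benjamini-Hochberg correction across the pair family at
    ``alpha``; per-pair raw significance is kept alongside.
    """
    labels = {n: assignment.labels[n] for n in network.nodes
              if n in assignment.labels.index}
    clusters = sorted(set(labels.values()))
    if len(clusters) < 2:
        raise ParameterError("cluster_pair_stats needs >=2 clusters")
    sizes = pd.Series(list(labels.values())).value_counts()
    nodes = list(labels)
    M = len(nodes) * (len(nodes) - 1) // 2
    edges = [(a, b) for a, b in network.edges if a in labels and b in labels]
    K = len(edges)
    counts: dict[tuple[str, str], int] = {}
    for a, b in edges:
        key = tuple(sorted((labels[a], labels[b])))
        counts[key] = counts.get(key, 0) + 1
    rows = []
    for c1, c2 in itertools.combinations_with_replacement(clusters, 2):
        x = counts.get((c1, c2), 0)
        if c1 == c2:
            n = sizes[c1] * (sizes[c1] - 1) // 2
        else:
            n = sizes[c1] * sizes[c2]
        p = float(stats.hypergeom.sf(x - 1, M, K, int(n))) if n else 1.0
        rows.append({"cluster_1": c1, "cluster_2": c2, "edges": x,
                     "n_pairs": int(n), "p": p})
    out = pd.DataFrame(rows)
    out["pct_all"] = 100.0 * out["edges"] / max(K, 1)
    inter = out["cluster_1"] != out["cluster_2"]
    inter_total = out.loc[inter, "edges"].sum()
    out["pct_inter"] = np.where(
        inter, 100.0 * out["edges"] / max(inter_total, 1), np.nan)
    out["significant"] = out["p"] < alpha
    # the flag controls the family-wise picture over all O(k^2) pairs
    out["q_bh"] = stats.false_discovery_control(out["p"], method="bh")
    out["flagged"] = out["q_bh"] < alpha

    if permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(out))
        sub = network.subgraph(nodes).copy()
        for _ in range(permutations):
            g = sub.copy()
            try:
                nx.double_edge_swap(g, nswap=2 * K, max_tries=40 * K + 10,
                                    seed=int(rng.integers(2 ** 31)))
            except nx.NetworkXError:
                pass
            perm_counts: dict[tuple[str, str], int] = {}
            for a, b in g.edges:
                key = tuple(sorted((labels[a], labels[b])))
                perm_counts[key] = perm_counts.get(key, 0) + 1
            for i, row in out.iterrows():
                key = (row["cluster_1"], row["cluster_2"])
                if perm_counts.get(key, 0) >= row["edges"]:
                    exceed[i] += 1
        out["p_rewire"] = (exceed + 1) / (permutations + 1)

    flagged = tuple(
        (r["cluster_1"], r["cluster_2"])
        for _, r in out[out["flagged"]].sort_values("p").iterrows())
    return ClusterPairStats(table=out.sort_values("p", kind="stable")
                            .reset_index(drop=True),
                            total_edges=K, flagged=flagged)


# ---------------------------------------------------------------------------
# Molecular-type interaction map
# ---------------------------------------------------------------------------

def type_interaction_map(network: nx.Graph, annotations: AnnotationTable,
                         assignment: ClusterAssignment,
                         fraction_threshold: float = 0.01,
                         alpha: float = 0.05) -> tuple[pd.DataFrame, nx.DiGraph]:
    """Summarize cross-type interactions as a directed type-level map.

    For each unordered pair of molecular types the interaction fraction is
    cross-type edges / (|type1| * |type2|); an edge is drawn when the
    fraction strictly exceeds the threshold.  Significance reuses the
    edge-universe hypergeometric at ``alpha``.  Direction goes from the type
    whose members sit earlier along the A->E flow (lower mean cluster rank)
    toward the later one; equal ranks leave the edge undirected.
    """
    typ = annotations.table["molecular_type"].reindex(
        assignment.retained).dropna()
    typ = typ[typ != "other/unknown"]
    typed_nodes = [n for n in network.nodes if n in typ.index]
    t_of = typ.loc[typed_nodes]
    sizes = t_of.value_counts()
    ranks = assignment.labels.map(CLUSTER_RANK)
    mean_rank = ranks.reindex(t_of.index).groupby(t_of).mean()

    M = len(typed_nodes) * (len(typed_nodes) - 1) // 2
    edges = [(a, b) for a, b in network.edges
             if a in t_of.index and b in t_of.index]
    K = len(edges)
    cross: dict[tuple[str, str], int] = {}
    for a, b in edges:
        key = tuple(sorted((t_of[a], t_of[b])))
        cross[key] = cross.get(key, 0) + 1

    rows = []
    graph = nx.DiGraph()
    graph.add_nodes_from(sizes.index)
    for t1, t2 in itertools.combinations(sorted(sizes.index), 2):
        n = int(sizes[t1] * sizes[t2])
        x = cross.get((t1, t2) if t1 < t2 else (t2, t1), 0)
        frac = x / n if n else 0.0
        keep = frac > fraction_threshold
        p = float(stats.hypergeom.sf(x - 1, M, K, n)) if n else 1.0
        r1, r2 = mean_rank.get(t1, np.nan), mean_rank.get(t2, np.nan)
        if not keep:
            direction = None
        elif np.isnan(r1) or np.isnan(r2) or r1 == r2:
            direction = "undirected"
        else:
            direction = f"{t1}->{t2}" if r1 < r2 else f"{t2}->{t1}"
        rows.append({"type_1": t1, "type_2": t2, "edges": x, "n_pairs": n,
                     "fraction": frac, "p": p, "significant": p < alpha,
                     "kept": keep, "direction": direction})
        if keep:
            if direction == "undirected":
                graph.add_edge(t1, t2, fraction=frac, p=p, undirected=True)
                graph.add_edge(t2, t1, fraction=frac, p=p, undirected=True)
            else:
                src, dst = direction.split("->")
                graph.add_edge(src, dst, fraction=frac, p=p, undirected=False)
    return pd.DataFrame(rows), graph


# ---------------------------------------------------------------------------
# Cascade enumeration and layout
# ---------------------------------------------------------------------------

@dataclass
class Cascade:
    """An ordered (C, D, E) protein triple linked by two PPI edges."""

    protein_c: str
    protein_d: str
    protein_e: str
    type_c: str | None = None
    type_d: str | None = None
    type_e: str | None = None
    compartment_c: str | None = None
    compartment_d: str | None = None
    compartment_e: str | None = None


def enumerate_cascades(network: nx.Graph, assignment: ClusterAssignment,
                       annotations: AnnotationTable | None = None,
                       from_label: str = "C", via_label: str = "D",
                       to_label: str = "E",
                       require_terminal_type: str | None = "transcription regulator",
                       ) -> pd.DataFrame:
    """All triples (c, d, e) with labels C/D/E and edges {c,d}, {d,e}, c != e.

    When ``require_terminal_type`` is set (default: transcription regulator,
    as in the published cascade table) the terminal member must carry that
    molecular type.  Output is sorted lexicographically by
    (Protein_D, Protein_E, Protein_C), mirroring the published grouping of
    C-members under each (D, E) pair.
    """
    have = set(assignment.labels.unique())
    for lab in (from_label, via_label, to_label):
        if lab not in have:
            raise AndrodynError(f"unknown cluster label {lab!r}")
    if require_terminal_type is not None and annotations is None:
        raise ParameterError(
            "require_terminal_type needs an annotation table")
    labels = assignment.labels
    in_net = [n for n in network.nodes if n in labels.index]
    lab_of = labels.loc[in_net]
    types = (annotations.table["molecular_type"] if annotations is not None
             else None)
    comps = (annotations.table["compartment"] if annotations is not None
             else None)

    def _ann(series, p):
        if series is None or p not in series.index:
            return None
        return series[p]

    rows = []
    for d in lab_of.index[lab_of == via_label]:
        nbrs = list(network.neighbors(d))
        cs = [n for n in nbrs if labels.get(n) == from_label]
        es = [n for n in nbrs if labels.get(n) == to_label]
        if require_terminal_type is not None:
            es = [e for e in es if _ann(types, e) == require_terminal_type]
        for c in cs:
            for e in es:
                if c == e:
                    continue
                rows.append({
                    "Protein_C": c, "Protein_D": d, "Protein_E": e,
                    "Type_C": _ann(types, c), "Type_D": _ann(types, d),
                    "Type_E": _ann(types, e),
                    "Compartment_C": _ann(comps, c),
                    "Compartment_D": _ann(comps, d),
                    "Compartment_E": _ann(comps, e),
                })
    out = pd.DataFrame(rows, columns=[
        "Protein_C", "Protein_D", "Protein_E", "Type_C", "Type_D", "Type_E",
        "Compartment_C", "Compartment_D", "Compartment_E"])
    return out.sort_values(["Protein_D", "Protein_E", "Protein_C"],
                           kind="stable").reset_index(drop=True)


def cascade_counts(cascades: pd.DataFrame) -> dict[str, int]:
    """Triple count and grouped (D, E)-row count of a cascade table."""
    return {
        "triples": int(len(cascades)),
        "de_groups": int(cascades.groupby(["Protein_D", "Protein_E"]).ngroups)
        if len(cascades) else 0,
    }


def cascade_layout(cascades: pd.DataFrame,
                   annotations: AnnotationTable,
                   row_map: dict[str, str] | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame, nx.DiGraph]:
    """Place cascade members on the 3x3 grid (cluster column x compartment row).

    Columns are the C, D, E clusters; rows plasma membrane / cytoplasm /
    nucleus.  Compartments without a dedicated row are mapped per
    ``row_map`` (default: extracellular space -> plasma membrane,
    other/unknown -> cytoplasm) with a log entry.  Returns the 3x3 region
    occupancy table (distinct proteins per region), the per-protein
    placement, and the directed C->D->E graph for export.
    """
    row_map = dict(DEFAULT_ROW_MAP if row_map is None else row_map)
    comp = annotations.table["compartment"]
    placements = {}
    for col, field in zip(CASCADE_COLUMNS,
                          ("Protein_C", "Protein_D", "Protein_E")):
        for p in cascades[field].unique() if len(cascades) else []:
            c = comp.get(p, "other/unknown")
            if c not in CASCADE_ROWS:
                mapped = row_map.get(c, "cytoplasm")
                log.info("cascade_layout: %s compartment %r mapped to row %r",
                         p, c, mapped)
                c = mapped
            placements[(p, col)] = c
    placement = pd.DataFrame(
        [{"protein": p, "column": col, "row": row}
         for (p, col), row in placements.items()])
    occupancy = pd.DataFrame(0, index=list(CASCADE_ROWS),
                             columns=list(CASCADE_COLUMNS))
    if len(placement):
        tab = placement.groupby(["row", "column"])["protein"].nunique()
        for (row, col), v in tab.items():
            occupancy.at[row, col] = int(v)
    graph = nx.DiGraph()
    for _, r in (cascades.iterrows() if len(cascades) else []):
        graph.add_edge(r["Protein_C"], r["Protein_D"])
        graph.add_edge(r["Protein_D"], r["Protein_E"])
    for (p, col), row in placements.items():
        if p in graph:
            graph.nodes[p]["column"] = col
            graph.nodes[p]["row"] = row
    return occupancy, placement, graph
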