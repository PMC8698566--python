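"""Fisher's-exact association between protein clusters and gene-set concepts.

Each (cluster, concept) pair is tested one-sided for enrichment on the 2x2
table over the labeled-protein universe; associations with p < 0.001 and
odds ratio > 2 are retained and assembled into a concept-map network whose
node sizes track concept size and edge thickness -log10 p.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .fcm import ClusterAssignment
from .io import GeneSetCollection

log = logging.getLogger("androdyn")


def fisher_associate(
    assignment: ClusterAssignment,
    concepts: GeneSetCollection,
    universe: pd.Index | None = None,
    alpha: float = 0.001,
    odds_ratio_floor: float = 2.0,
) -> pd.DataFrame:
    """One-sided Fisher's exact test for every (cluster, concept) pair.

    The universe defaults to the labeled proteins.  The 2x2 cells are
    a = in-cluster & in-concept, b = in-cluster only, c = in-concept only,
    d = neither; the sample odds ratio ad/bc is reported (inf when bc = 0;
    a Haldane-Anscombe 0.5-corrected value is added and flagged whenever a
    zero cell occurs).  Retention requires p < alpha and OR > floor.
    Concepts disjoint from the universe are skipped with a warning.
    """
    if universe is None:
        universe = assignment.retained
    universe = pd.Index(universe)
    labels = assignment.labels.reindex(universe).dropna()
    rows = []
    for name, members in concepts:
        in_concept = universe.isin(members)
        if not in_concept.any():
            log.warning("fisher_associate: concept %r disjoint from universe",
                        name)
            continue
        concept_idx = set(universe[in_concept])
        for cluster in sorted(labels.unique()):
            cl = set(labels.index[labels == cluster])
            a = len(cl & concept_idx)
            b = len(cl) - a
            c = len(concept_idx) - a
            d = len(universe) - a - b - c
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            if b * c == 0:
                odds = np.inf if a * d > 0 else np.nan
                odds_hald = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
                corrected = True
            else:
                odds = (a * d) / (b * c)
                odds_hald = odds
                corrected = False
            retained = (p < alpha) and (odds_hald if corrected else odds) \
                > odds_ratio_floor
            rows.append({"cluster": cluster, "concept": name, "a": a, "b": b,
                         "c": c, "d": d, "odds_ratio": odds,
                         "odds_ratio_haldane": odds_hald,
                         "zero_cell_corrected": corrected,
                         "p": float(p), "retained": bool(retained)})
    out = pd.DataFrame(rows, columns=["cluster", "concept", "a", "b", "c",
                                      "d", "odds_ratio",
                                      "odds_ratio_haldane",
                                      "zero_cell_corrected", "p", "retained"])
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def build_concept_map(associations: pd.DataFrame,
                      concepts: GeneSetCollection,
                      assignment: ClusterAssignment) -> nx.Graph:
    """Bipartite cluster-concept network of the retained associations.

    Cluster nodes always appear (isolated when nothing is retained); concept
    nodes carry size = gene count, edges thickness = -log10 p.
    """
    graph = nx.Graph()
    for cluster in sorted(assignment.labels.unique()):
        graph.add_node(f"cluster:{cluster}", kind="cluster",
                       size=int((assignment.labels == cluster).sum()))
    kept = associations[associations["retained"]]
    for _, r in kept.iterrows():
        cname = f"concept:{r['concept']}"
        if cname not in graph:
            graph.add_node(cname, kind="concept",
                           size=len(concepts.sets[r["concept"]]),
                           source=concepts.sources.get(r["concept"], ""))
        thickness = float(-np.log10(max(r["p"], 1e-300)))
        graph.add_edge(f"cluster:{r['cluster']}", cname,
                       thickness=thickness, p=float(r["p"]))
    return graph
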