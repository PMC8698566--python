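"""Hypergeometric over-representation of annotations within clusters.

For a cluster of size n drawn from a universe of M annotated proteins of
which K carry the category, the enrichment p-value is the upper tail
P[X >= x] of Hypergeometric(M, K, n).  Only enrichment (not depletion) is
tested and raw p-values are thresholded, matching common practice for this
kind of compartment/type profiling; a Benjamini-Hochberg column is emitted
for transparency.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats

from .errors import ParameterError, PipelineError
from .fcm import ClusterAssignment
from .io import AnnotationTable, COMPARTMENTS, MOLECULAR_TYPES

log = logging.getLogger("androdyn")

_KINDS = {"compartment": COMPARTMENTS, "molecular_type": MOLECULAR_TYPES}


def _annotated_universe(assignment: ClusterAssignment,
                        annotations: AnnotationTable, kind: str) -> pd.Series:
    """Annotations of retained proteins, unknown category excluded."""
    if kind not in _KINDS:
        raise ParameterError(f"kind must be one of {sorted(_KINDS)}")
    ann = annotations.table[kind].reindex(assignment.retained).dropna()
    ann = ann[ann != "other/unknown"]
    if ann.empty:
        raise PipelineError(f"empty {kind} universe")
    return ann


def hypergeom_enrich(
    assignment: ClusterAssignment,
    annotations: AnnotationTable,
    kind: str = "compartment",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment for every (cluster, category).

    The universe is the retained (labeled) protein set carrying an
    annotation of the requested kind.  Returns one row per pair with counts
    (x, n, K, M), p-value, fold enrichment (x/n)/(K/M), a BH-adjusted column
    and the significance flag at ``alpha``; sorted by p-value.
    """
    ann = _annotated_universe(assignment, annotations, kind)
    labels = assignment.labels.reindex(ann.index)
    M = len(ann)
    rows = []
    for cluster, members in labels.groupby(labels):
        n = len(members)
        in_cluster = ann.loc[members.index]
        for category, K in ann.value_counts().items():
            x = int((in_cluster == category).sum())
            p = float(stats.hypergeom.sf(x - 1, M, int(K), n))
            fold = (x / n) / (K / M)
            rows.append({"cluster": cluster, "category": category,
                         "kind": kind, "x": x, "n": n, "K": int(K), "M": M,
                         "p": p, "fold": fold})
    out = pd.DataFrame(rows)
    out["q_bh"] = stats.false_discovery_control(out["p"], method="bh")
    out["significant"] = out["p"] < alpha
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def composition_profile(
    assignment: ClusterAssignment,
    annotations: AnnotationTable,
    kind: str = "compartment",
) -> pd.DataFrame:
    """Per-cluster category percentages (rows clusters, columns categories).

    Percentages are over annotated cluster members and sum to 100 per
    cluster; 'other/unknown' is kept here (it is a composition, not a test).
    """
    if kind not in _KINDS:
        raise ParameterError(f"kind must be one of {sorted(_KINDS)}")
    ann = annotations.table[kind].reindex(assignment.retained).dropna()
    labels = assignment.labels.reindex(ann.index)
    counts = pd.crosstab(labels, ann)
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    pct.index.name = "cluster"
    return pct


def composition_long(pct: pd.DataFrame) -> pd.DataFrame:
    """Strip-chart-ready long format of a composition table."""
    long = pct.reset_index().melt(id_vars="cluster", var_name="category",
                                  value_name="percent")
    return long.sort_values(["cluster", "category"]).reset_index(drop=True)
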