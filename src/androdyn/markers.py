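"""Consensus differential-expression marker calling across datasets.

Each expression dataset is normalized per array (log, median-centered, unit
standard deviation), tested gene-wise with a two-sample t-test, and a gene
becomes a consensus marker when it is significant with the same direction in
at least two independent datasets.  Paired tumor/normal cohorts use a paired
t-test by default (the printed analysis used an unpaired test; that mode is
available as ``method="unpaired"``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, ParameterError
from .fcm import ClusterAssignment
from .preprocess import zscore_matrix

log = logging.getLogger("androdyn")


@dataclass
class ExpressionDataset:
    """Genes x samples matrix with group labels and optional pair ids."""

    values: pd.DataFrame          # index gene, columns sample ids
    groups: pd.Series             # per sample: case/control label
    dataset_id: str
    pairs: pd.Series | None = None  # per sample: pair id for matched designs
    case_label: str = "case"
    control_label: str = "control"

    def __post_init__(self) -> None:
        if not self.groups.index.equals(pd.Index(self.values.columns)):
            self.groups = self.groups.reindex(self.values.columns)
        counts = self.groups.value_counts()
        for lab in (self.case_label, self.control_label):
            if counts.get(lab, 0) < 2:
                raise ParameterError(
                    f"{self.dataset_id}: group {lab!r} needs >=2 samples")

    def to_tsv(self, path) -> None:
        """Two-row header: group then pair id, then the matrix."""
        with open(path, "w") as fh:
            fh.write("gene\t" + "\t".join(map(str, self.values.columns)) + "\n")
            fh.write("#group\t" + "\t".join(self.groups.astype(str)) + "\n")
            pairs = (self.pairs.astype(str) if self.pairs is not None
                     else pd.Series("", index=self.values.columns))
            fh.write("#pair\t" + "\t".join(pairs.reindex(self.values.columns)
                                           .fillna("")) + "\n")
        self.values.to_csv(path, sep="\t", mode="a", header=False)

    @classmethod
    def from_tsv(cls, path, dataset_id: str | None = None,
                 case_label: str = "case", control_label: str = "control"
                 ) -> "ExpressionDataset":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            grp_line = fh.readline().rstrip("\n").split("\t")
            pair_line = fh.readline().rstrip("\n").split("\t")
        if header[0] != "gene" or grp_line[0] != "#group" \
                or pair_line[0] != "#pair":
            raise FormatError(f"{path}: not an expression TSV "
                              "(gene/#group/#pair header expected)")
        samples = header[1:]
        groups = pd.Series(grp_line[1:], index=samples)
        pairs = pd.Series(pair_line[1:], index=samples)
        pairs = None if (pairs == "").all() else pairs
        values = pd.read_csv(path, sep="\t", skiprows=3, header=None,
                             index_col=0)
        values.index.name = "gene"
        values.columns = samples
        return cls(values=values, groups=groups,
                   dataset_id=dataset_id or str(path), pairs=pairs,
                   case_label=case_label, control_label=control_label)


def normalize_dataset(ds: ExpressionDataset, log_transform: bool = True
                      ) -> ExpressionDataset:
    """Log-transform, median-center each array, scale each array to sd 1.

    Values <= 0 are handled by a logged additive offset before the log.
    Constant arrays cannot be scaled and are dropped with a warning.
    """
    vals = ds.values.astype(float)
    if log_transform:
        lo = vals.min().min()
        if lo <= 0:
            offset = 1.0 - lo
            log.info("normalize_dataset[%s]: shifting by %.4g before log",
                     ds.dataset_id, offset)
            vals = vals + offset
        vals = np.log2(vals)
    med = vals.median(axis=0)
    vals = vals.sub(med, axis=1)
    sd = vals.std(axis=0, ddof=1)
    const = sd == 0
    if const.any():
        log.warning("normalize_dataset[%s]: dropped %d constant arrays",
                    ds.dataset_id, int(const.sum()))
        vals = vals.loc[:, ~const]
        sd = sd[~const]
    vals = vals.div(sd, axis=1)
    return ExpressionDataset(values=vals, groups=ds.groups.loc[vals.columns],
                             dataset_id=ds.dataset_id,
                             pairs=(ds.pairs.loc[vals.columns]
                                    if ds.pairs is not None else None),
                             case_label=ds.case_label,
                             control_label=ds.control_label)


def dataset_de(ds: ExpressionDataset, alpha: float = 0.05,
               welch: bool = False) -> pd.DataFrame:
    """Two-sample t-test per gene; direction = sign(case mean - control mean)."""
    case = ds.values.loc[:, ds.groups == ds.case_label].to_numpy(float)
    ctrl = ds.values.loc[:, ds.groups == ds.control_label].to_numpy(float)
    t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=not welch)
    diff = case.mean(axis=1) - ctrl.mean(axis=1)
    out = pd.DataFrame({
        "t": t, "p": p, "mean_diff": diff,
        "direction": np.where(diff > 0, "up",
                              np.where(diff < 0, "down", "none")),
    }, index=ds.values.index)
    out["significant"] = (out["p"] < alpha) & (out["direction"] != "none")
    out["dataset"] = ds.dataset_id
    return out


def consensus_markers(de_tables: list[pd.DataFrame], min_datasets: int = 2
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call genes significant in the same direction in >= ``min_datasets``.

    Returns (markers, conflicts): markers has gene, direction, n_support and
    the supporting dataset ids; conflicts lists genes significant in both
    directions somewhere but reaching consensus in neither.
    """
    calls = pd.concat([t[t["significant"]][["dataset", "direction"]]
                       .assign(gene=t.index[t["significant"]])
                       for t in de_tables], ignore_index=True)
    if calls.empty:
        empty = pd.DataFrame(columns=["gene", "direction", "n_support",
                                      "datasets"])
        return empty, empty.copy()
    support = (calls.groupby(["gene", "direction"])
               .agg(n_support=("dataset", "nunique"),
                    datasets=("dataset", lambda s: ",".join(sorted(set(s)))))
               .reset_index())
    consensus = support[support["n_support"] >= min_datasets]
    # a gene reaching consensus in both directions is contradictory: demote
    both = consensus["gene"].value_counts()
    contradictory = set(both[both > 1].index)
    markers = (consensus[~consensus["gene"].isin(contradictory)]
               .sort_values(["direction", "gene"]).reset_index(drop=True))
    seen_dirs = support.groupby("gene")["direction"].nunique()
    conflict_genes = set(seen_dirs[seen_dirs > 1].index) | contradictory
    conflicts = (support[support["gene"].isin(conflict_genes
                                              - set(markers["gene"]))]
                 .sort_values(["gene", "direction"]).reset_index(drop=True))
    return markers[["gene", "direction", "n_support", "datasets"]], conflicts


def paired_de(ds: ExpressionDataset, alpha: float = 0.01,
              method: str = "paired") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tumor-vs-normal test per gene on a matched cohort.

    ``method="paired"`` (default) runs a paired t-test on the pair-matched
    sample columns; ``method="unpaired"`` runs the plain two-sample test.
    Also returns the per-gene z-score matrix for heatmapping.
    """
    if method not in {"paired", "unpaired"}:
        raise ParameterError(f"unknown method {method!r}")
    if method == "paired":
        if ds.pairs is None:
            raise ParameterError("paired test needs pair ids")
        case_cols, ctrl_cols = [], []
        for pid, cols in ds.pairs.groupby(ds.pairs).groups.items():
            g = ds.groups.loc[cols]
            c_case = g.index[g == ds.case_label]
            c_ctrl = g.index[g == ds.control_label]
            if len(c_case) == 1 and len(c_ctrl) == 1:
                case_cols.append(c_case[0])
                ctrl_cols.append(c_ctrl[0])
            else:
                log.warning("paired_de[%s]: pair %r incomplete, skipped",
                            ds.dataset_id, pid)
        case = ds.values[case_cols].to_numpy(float)
        ctrl = ds.values[ctrl_cols].to_numpy(float)
        t, p = stats.ttest_rel(case, ctrl, axis=1)
        diff = (case - ctrl).mean(axis=1)
        out = pd.DataFrame({"t": t, "p": p, "mean_diff": diff},
                           index=ds.values.index)
    else:
        out = dataset_de(ds, alpha=alpha)[["t", "p", "mean_diff"]]
    out["direction"] = np.where(out["mean_diff"] > 0, "up",
                                np.where(out["mean_diff"] < 0, "down", "none"))
    out["significant"] = (out["p"] < alpha) & (out["direction"] != "none")
    out["dataset"] = ds.dataset_id
    zmat = zscore_matrix(ds.values, axis=1)
    return out, zmat


def intersect_with_clusters(markers: pd.DataFrame,
                            assignment: ClusterAssignment
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join consensus markers onto the cluster assignment by gene symbol.

    Returns (long_table, per_cluster_counts); the long table has one row per
    (gene, cluster, dataset, direction), mirroring a genes-by-datasets
    marker heatmap grouped by cluster.
    """
    joined = markers[markers["gene"].isin(assignment.labels.index)].copy()
    if joined.empty:
        log.warning("intersect_with_clusters: no marker symbol matches a "
                    "clustered protein")
        return (pd.DataFrame(columns=["gene", "cluster", "dataset",
                                      "direction"]),
                pd.DataFrame(columns=["cluster", "up", "down"]))
    joined["cluster"] = assignment.labels.reindex(joined["gene"]).to_numpy()
    long_rows = []
    for _, r in joined.iterrows():
        for dsid in str(r["datasets"]).split(","):
            long_rows.append({"gene": r["gene"], "cluster": r["cluster"],
                              "dataset": dsid, "direction": r["direction"]})
    long = pd.DataFrame(long_rows).sort_values(
        ["cluster", "gene", "dataset"]).reset_index(drop=True)
    counts = (joined.pivot_table(index="cluster", columns="direction",
                                 values="gene", aggfunc="nunique",
                                 fill_value=0)
              .reindex(columns=["up", "down"], fill_value=0)
              .reset_index())
    return long, counts
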