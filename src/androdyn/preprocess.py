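"""From raw treated/vehicle quantification to standardized time profiles.

The chain mirrors classic time-course TMT practice: per-sample median
centering of the ratio columns, arithmetic averaging over the replicate
ratios, log2 transform, then a per-protein z-score across the time points.
Replicate quality is summarised by a PCA of the per-sample value vectors and
the silhouette of replicates grouped by time point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .errors import ParameterError, PipelineError
from .io import RatioTable

log = logging.getLogger("androdyn")


@dataclass
class TimeProfileMatrix:
    """Standardized per-protein profiles; the fuzzy clustering input.

    Each row has mean 0 and unit variance across the D time points.
    """

    profiles: pd.DataFrame  # index protein_id, columns time points (sorted)
    ddof: int = 1

    def __post_init__(self) -> None:
        if self.profiles.shape[1] < 2:
            raise ParameterError("need at least 2 time dimensions")
        arr = self.profiles.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ParameterError("TimeProfileMatrix must not contain NaN")
        mu = arr.mean(axis=1)
        var = arr.var(axis=1, ddof=self.ddof)
        if not (np.all(np.abs(mu) < 1e-9) and np.all(np.abs(var - 1) < 1e-9)):
            raise ParameterError("profiles must be row-standardized")

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.profiles.columns, dtype=float)

    @property
    def n_proteins(self) -> int:
        return self.profiles.shape[0]

    @property
    def n_dims(self) -> int:
        return self.profiles.shape[1]

    def to_tsv(self, path) -> None:
        out = self.profiles.copy()
        out.index.name = "protein_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "TimeProfileMatrix":
        df = pd.read_csv(path, sep="\t", index_col="protein_id")
        df.columns = pd.Index([int(float(c)) for c in df.columns],
                              name="time")
        return cls(df)


@dataclass
class QCReport:
    """Per-sample PCA coordinates plus a replicate-grouping score."""

    coordinates: pd.DataFrame      # index sample label, columns PC1, PC2
    explained_variance: np.ndarray  # fractions, non-increasing
    silhouette: float | None        # replicates grouped by time point


def filter_quantified(
    table: RatioTable,
    min_unique_peptides: int = 2,
    require_all_replicates: bool = True,
) -> RatioTable:
    """Keep proteins with enough unique peptides and (optionally) a value in
    every (condition, time, replicate) cell."""
    keep = table.unique_peptides >= min_unique_peptides
    if require_all_replicates:
        keep &= table.values.notna().all(axis=1)
    kept, dropped = int(keep.sum()), int((~keep).sum())
    log.info("filter_quantified: retained %d, dropped %d", kept, dropped)
    if kept == 0:
        raise PipelineError(
            "no protein passed quantification filters; review "
            "min_unique_peptides / require_all_replicates")
    return RatioTable(values=table.values.loc[keep],
                      unique_peptides=table.unique_peptides.loc[keep])


def compute_ratios(table: RatioTable) -> pd.DataFrame:
    """Treated / vehicle ratio at each matched (time, replicate).

    Proteins with a zero or missing vehicle value are dropped with a log
    entry.  Time 0 divides the two aliquots of the untreated baseline, so the
    ratio is ~1 by construction when the same control sample was split.
    """
    treated = table.values["treated"]
    vehicle = table.values["vehicle"]
    missing_cols = set(treated.columns) ^ set(vehicle.columns)
    if missing_cols:
        raise PipelineError(
            f"conditions not matched at (time, replicate): {sorted(missing_cols)}")
    vehicle = vehicle[treated.columns]
    ok = vehicle.notna().all(axis=1) & (vehicle > 0).all(axis=1) \
        & treated.notna().all(axis=1)
    if (~ok).any():
        log.warning("compute_ratios: dropped %d proteins with zero/missing "
                    "vehicle or treated values", int((~ok).sum()))
    ratios = treated.loc[ok] / vehicle.loc[ok]
    ratios.columns.names = ["time", "replicate"]
    return ratios


def standardize_profiles(
    ratios: pd.DataFrame,
    median_center: bool = True,
    average: str = "arithmetic",
    ddof: int = 1,
) -> TimeProfileMatrix:
    """Median-center per sample, average replicates, log2, z-score per protein.

    Constant (zero-variance) profiles cannot be standardized and are removed
    with a log entry, as are proteins whose centered values are non-positive.
    """
    if ratios.shape[1] < 2:
        raise ParameterError("need >=2 time points")
    mat = ratios.copy()
    if median_center:
        mat = mat / mat.median(axis=0)
    pos = (mat > 0).all(axis=1)
    if (~pos).any():
        log.warning("standardize_profiles: dropped %d proteins with "
                    "non-positive centered values", int((~pos).sum()))
        mat = mat.loc[pos]
    if average == "arithmetic":
        avg = mat.T.groupby(level="time").mean().T
    elif average == "geometric":
        avg = np.exp(np.log(mat).T.groupby(level="time").mean().T)
    else:
        raise ParameterError(f"unknown replicate average {average!r}")
    logged = np.log2(avg)
    sd = logged.std(axis=1, ddof=ddof)
    nonconst = sd > 0
    if (~nonconst).any():
        log.warning("standardize_profiles: dropped %d zero-variance profiles",
                    int((~nonconst).sum()))
    logged = logged.loc[nonconst]
    z = logged.sub(logged.mean(axis=1), axis=0).div(sd.loc[nonconst], axis=0)
    z = z[sorted(z.columns)]
    return TimeProfileMatrix(z, ddof=ddof)


def pca_qc(table: RatioTable) -> QCReport:
    """PCA of the per-sample value vectors with a replicate-grouping score.

    Samples are all (condition, time, replicate) columns; the grouping score
    is the mean silhouette of replicates grouped by (condition, time) on the
    first two components.  With fewer than 3 complete samples QC is skipped.
    """
    vals = table.values.dropna(axis=0)
    if vals.shape[1] < 3 or vals.shape[0] < 3:
        log.warning("pca_qc: skipped (fewer than 3 samples or proteins)")
        return QCReport(pd.DataFrame(columns=["PC1", "PC2"]),
                        np.array([]), None)
    X = np.log2(vals.to_numpy(dtype=float)).T  # samples x proteins
    X = X - X.mean(axis=0)
    n_comp = min(2, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(X)
    labels = [f"{c}_t{t}_r{r}" for c, t, r in vals.columns]
    groups = [f"{c}_t{t}" for c, t, r in vals.columns]
    coord_df = pd.DataFrame(coords[:, :2],
                            columns=["PC1", "PC2"][: coords.shape[1]],
                            index=labels)
    sil = None
    if len(set(groups)) >= 2 and all(
            pd.Series(groups).value_counts() >= 2):
        uniq = coord_df.drop_duplicates()
        if len(uniq) > len(set(groups)):
            sil = float(silhouette_score(coord_df.to_numpy(), groups))
        else:
            # replicates coincide exactly: perfect grouping by convention
            sil = 1.0
    return QCReport(coord_df, pca.explained_variance_ratio_, sil)


def zscore_matrix(df: pd.DataFrame, axis: int = 1, ddof: int = 1) -> pd.DataFrame:
    """Row- or column-wise z-score helper used by heatmap exports."""
    arr = stats.zscore(df.to_numpy(dtype=float), axis=axis, ddof=ddof)
    return pd.DataFrame(arr, index=df.index, columns=df.columns)
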