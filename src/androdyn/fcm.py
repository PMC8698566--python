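"""Fuzzy c-means clustering of standardized time profiles.

The model follows the classic Bezdek iteration: centroids are membership-
weighted means, memberships are inverse-distance ratios raised to
2/(m-1), and the objective J = sum_ic U_ic^m ||x_i - v_c||^2 decreases
monotonically.  The fuzzifier m is estimated from the data dimensions with
the minimum-fuzzifier rule commonly used for omics time courses:

    m = 1 + (1418/N + 22.05) * D^-2
          + (12.33/N + 0.243) * D^(-0.0406 ln N - 0.1134)

where N is the number of profiles and D the number of time dimensions.
Cluster count is chosen by the elbow of J(k) (maximum second-order
difference), proteins with maximum membership at or below the threshold
(default 0.4) are set aside as fuzzy/uncertain, and for k=5 the clusters are
given the archetype letters A-E (signal initiators, early stimulators,
signal mediators, late stimulators, terminal regulators) from their centroid
shapes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .preprocess import TimeProfileMatrix

log = logging.getLogger("androdyn")

ARCHETYPE_LETTERS = ("A", "B", "C", "D", "E")


def estimate_fuzzifier(n_profiles: int, n_dims: int) -> float:
    """Minimum usable fuzzifier for an N x D profile matrix.

    Returns the raw value; round to two decimals for reporting.  Both
    correction terms vanish as D grows, so m decreases toward 1.
    """
    if n_profiles < 3:
        raise ParameterError("need at least 3 profiles")
    if n_dims < 2:
        raise ParameterError("need at least 2 dimensions")
    N, D = float(n_profiles), float(n_dims)
    term1 = (1418.0 / N + 22.05) * D ** -2.0
    term2 = (12.33 / N + 0.243) * D ** (-0.0406 * math.log(N) - 0.1134)
    return 1.0 + term1 + term2


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

@dataclass
class FcmParams:
    m: float
    k: int
    max_iter: int = 300
    tol: float = 1e-6
    seed: int = 0
    n_restarts: int = 5

    def __post_init__(self) -> None:
        if self.m <= 1:
            raise ParameterError("fuzzifier m must exceed 1")
        if self.k < 2:
            raise ParameterError("k must be >= 2")
        if self.tol <= 0:
            raise ParameterError("tol must be positive")


class FuzzyCMeans:
    """Fuzzy c-means model over a standardized profile matrix.

    Parameters
    ----------
    profiles : TimeProfileMatrix or DataFrame
        Row-standardized profiles (rows proteins, columns time points).

    ``fit(k=...)`` returns a :class:`FuzzyCMeansResults`.  When ``m`` is not
    supplied it is estimated from the data dimensions.
    """

    def __init__(self, profiles):
        if isinstance(profiles, TimeProfileMatrix):
            self._frame = profiles.profiles
        elif isinstance(profiles, pd.DataFrame):
            self._frame = profiles
        else:
            self._frame = pd.DataFrame(np.asarray(profiles, dtype=float))
        self.exog = self._frame.to_numpy(dtype=float)
        if np.isnan(self.exog).any():
            raise ParameterError("profiles contain missing values")
        self.ids = self._frame.index
        self.times = np.asarray(self._frame.columns, dtype=float)
        self.nobs, self.n_dims = self.exog.shape

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FuzzyCMeans":
        return cls(df)

    # -- fitting -----------------------------------------------------------
    def fit(self, k: int, m: float | None = None, max_iter: int = 300,
            tol: float = 1e-6, seed: int = 0, n_restarts: int = 5
            ) -> "FuzzyCMeansResults":
        if k >= self.nobs:
            raise ParameterError(f"k={k} must be < number of profiles {self.nobs}")
        if m is None:
            m = estimate_fuzzifier(self.nobs, self.n_dims)
        params = FcmParams(m=m, k=k, max_iter=max_iter, tol=tol, seed=seed,
                           n_restarts=n_restarts)
        rng = np.random.default_rng(seed)
        best = None
        for _ in range(max(1, n_restarts)):
            run = self._fit_once(params, rng)
            if best is None or run[2] < best[2]:
                best = run
        U, V, J, n_iter, converged, curve = best
        if not converged:
            log.warning("fcm: not converged after %d iterations (k=%d)",
                        n_iter, k)
        return FuzzyCMeansResults(model=self, params=params, membership=U,
                                  centroids=V, objective=J, n_iter=n_iter,
                                  converged=converged, objective_curve=curve)

    def _fit_once(self, p: FcmParams, rng: np.random.Generator):
        X = self.exog
        U = rng.dirichlet(np.ones(p.k), size=self.nobs)
        expo = 2.0 / (p.m - 1.0)
        J_prev = np.inf
        curve: list[float] = []
        converged = False
        for it in range(1, p.max_iter + 1):
            Um = U ** p.m
            V = (Um.T @ X) / Um.sum(axis=0)[:, None]
            d2 = ((X[:, None, :] - V[None, :, :]) ** 2).sum(axis=2)
            J = float((Um * d2).sum())
            curve.append(J)
            # J is non-increasing up to numerical noise
            assert J <= J_prev + 1e-8 * max(1.0, abs(J_prev)), \
                "FCM objective increased"
            J_prev = J
            # a point coincident with a centroid gets full membership there
            zero = d2 <= 1e-300
            with np.errstate(divide="ignore", invalid="ignore"):
                w = d2 ** (-expo / 2.0)
                U_new = np.where(zero.any(axis=1)[:, None],
                                 zero / np.maximum(zero.sum(axis=1)[:, None], 1),
                                 w / w.sum(axis=1)[:, None])
            delta = float(np.abs(U_new - U).max())
            U = U_new
            if delta < p.tol:
                converged = True
                break
        Um = U ** p.m
        V = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - V[None, :, :]) ** 2).sum(axis=2)
        J = float((Um * d2).sum())
        return U, V, J, it, converged, np.asarray(curve)


@dataclass
class ClusterAssignment:
    """Hard labels after the membership filter.

    ``labels`` maps retained protein ids to their cluster label (A-E or
    ``cluster_i``); ``max_membership`` is the winning membership value;
    ``excluded`` holds the fuzzy proteins (max membership <= threshold).
    """

    labels: pd.Series
    max_membership: pd.Series
    excluded: pd.Index
    threshold: float

    def __post_init__(self) -> None:
        assert self.labels.index.equals(self.max_membership.index)

    @property
    def retained(self) -> pd.Index:
        return self.labels.index

    def members(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def to_tsv(self, path) -> None:
        out = pd.DataFrame({"cluster": self.labels,
                            "max_membership": self.max_membership})
        out.index.name = "protein_id"
        out.to_csv(path, sep="\t")


@dataclass
class FuzzyCMeansResults:
    """Fitted fuzzy partition: membership matrix, centroids and objective."""

    model: FuzzyCMeans
    params: FcmParams
    membership: np.ndarray       # N x k, rows sum to 1
    centroids: np.ndarray        # k x D
    objective: float
    n_iter: int
    converged: bool
    objective_curve: np.ndarray = field(repr=False, default=None)

    @property
    def k(self) -> int:
        return self.params.k

    @property
    def membership_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.membership, index=self.model.ids,
                            columns=[f"cluster_{i + 1}" for i in range(self.k)])

    def assign(self, threshold: float = 0.4,
               labels: dict[int, str] | None = None) -> ClusterAssignment:
        """Hard-assign by argmax membership, excluding fuzzy proteins.

        Retains proteins with maximum membership strictly greater than
        ``threshold``; argmax ties break toward the lowest cluster index.
        ``labels`` optionally renames raw indices (e.g. the A-E archetypes).
        """
        maxm = self.membership.max(axis=1)
        arg = self.membership.argmax(axis=1)  # first (lowest) index on ties
        if (self.membership == maxm[:, None]).sum(axis=1).max() > 1:
            log.info("assign: argmax ties broken toward lowest cluster index")
        keep = maxm > threshold
        if labels is None:
            labels = {i: f"cluster_{i + 1}" for i in range(self.k)}
        lab = pd.Series([labels[a] for a in arg[keep]],
                        index=self.model.ids[keep], name="cluster")
        return ClusterAssignment(
            labels=lab,
            max_membership=pd.Series(maxm[keep], index=self.model.ids[keep]),
            excluded=self.model.ids[~keep],
            threshold=threshold,
        )

    def label_archetypes(self) -> dict[int, str]:
        """Map raw cluster indices to the A-E archetype letters (k=5 only)."""
        return label_clusters(self.centroids, self.model.times)

    def assign_archetypes(self, threshold: float = 0.4) -> ClusterAssignment:
        return self.assign(threshold=threshold, labels=self.label_archetypes())

    def summary(self) -> str:
        lines = [
            "Fuzzy C-Means Results",
            "=" * 52,
            f"{'No. profiles:':<24}{self.model.nobs}",
            f"{'Time dimensions:':<24}{self.model.n_dims}",
            f"{'Clusters (k):':<24}{self.k}",
            f"{'Fuzzifier (m):':<24}{self.params.m:.4f}",
            f"{'Objective (J):':<24}{self.objective:.6g}",
            f"{'Iterations:':<24}{self.n_iter}",
            f"{'Converged:':<24}{self.converged}",
            "-" * 52,
            f"{'cluster':<12}{'size(argmax)':>14}{'mean max U':>14}",
        ]
        arg = self.membership.argmax(axis=1)
        maxm = self.membership.max(axis=1)
        for c in range(self.k):
            sel = arg == c
            lines.append(f"{'cluster_' + str(c + 1):<12}{int(sel.sum()):>14}"
                         f"{(maxm[sel].mean() if sel.any() else float('nan')):>14.3f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Cluster-count selection and archetype labeling
# ---------------------------------------------------------------------------

def select_k_elbow(profiles, k_range=range(2, 11), m: float | None = None,
                   seed: int = 0, n_restarts: int = 5, max_iter: int = 300,
                   tol: float = 1e-6) -> tuple[int, pd.DataFrame]:
    """Pick k at the elbow of the FCM objective curve.

    The curve is anchored at the k=1 baseline (total scatter around the
    global centroid, where FCM degenerates to a single hard cluster) and the
    elbow is the k maximizing the second-order difference of log J,
    log J(k-1) - 2 log J(k) + log J(k+1): the point where the relative
    per-cluster gain collapses.  The log scale removes the geometric decay
    of J that otherwise drags a raw second difference toward the smallest k,
    and the k=1 anchor makes the smallest requested k eligible.  If no k has
    a positive second difference (a monotone-flat curve) the smallest k is
    returned with a warning.  The full J(k) table is returned for plotting.
    """
    ks = sorted(k_range)
    if len(ks) < 3:
        raise ParameterError("k_range needs at least 3 values")
    model = profiles if isinstance(profiles, FuzzyCMeans) else FuzzyCMeans(profiles)
    X = model.exog
    J1 = float(((X - X.mean(axis=0)) ** 2).sum())
    rows = [{"k": 1, "J": J1, "converged": True}]
    for k in ks:
        res = model.fit(k=k, m=m, seed=seed, n_restarts=n_restarts,
                        max_iter=max_iter, tol=tol)
        rows.append({"k": k, "J": res.objective, "converged": res.converged})
    diag = pd.DataFrame(rows).set_index("k")
    logJ = np.log(diag["J"])
    kk = list(diag.index)
    second = pd.Series(
        {k: logJ[kk[i - 1]] - 2 * logJ[k] + logJ[kk[i + 1]]
         for i, k in enumerate(kk) if 0 < i < len(kk) - 1})
    diag["log_second_diff"] = second.reindex(diag.index)
    if (second <= 0).all():
        log.warning("select_k_elbow: no positive second difference; "
                    "returning smallest k")
        return ks[0], diag
    return int(second.idxmax()), diag


def filter_membership(partition: FuzzyCMeansResults,
                      threshold: float = 0.4) -> ClusterAssignment:
    """Functional form of :meth:`FuzzyCMeansResults.assign` (unlabeled)."""
    return partition.assign(threshold=threshold)


def label_clusters(centroids: np.ndarray, times) -> dict[int, str]:
    """Name five centroids A-E from their temporal shape.

    The bimodal centroid (elevated at both ends, low in the middle) becomes
    C; the remaining four are ordered by their softmax-weighted time center
    of mass and named A, B, D, E from early to late.  For k != 5 generic
    ``cluster_i`` names are returned with a warning.
    """
    V = np.asarray(centroids, dtype=float)
    k, D = V.shape
    if k != 5:
        log.warning("label_clusters: k=%d != 5; using generic labels", k)
        return {i: f"cluster_{i + 1}" for i in range(k)}
    t = np.asarray(times, dtype=float)
    mid = D // 2
    bimod = np.minimum(V[:, :2].max(axis=1), V[:, -2:].max(axis=1)) - V[:, mid]
    if bimod.max() > 0:
        c_idx = int(bimod.argmax())
    else:
        log.warning("label_clusters: no centroid with positive bimodality; "
                    "C taken as the least unimodal")
        c_idx = int(bimod.argmax())
    w = np.exp(V - V.max(axis=1, keepdims=True))
    w /= w.sum(axis=1, keepdims=True)
    tbar = w @ t
    rest = sorted((i for i in range(5) if i != c_idx), key=lambda i: tbar[i])
    mapping = {c_idx: "C"}
    for letter, i in zip(("A", "B", "D", "E"), rest):
        mapping[i] = letter
    log.info("label_clusters: mapping %s (tbar=%s, bimodality=%s)",
             mapping, np.round(tbar, 2).tolist(), np.round(bimod, 2).tolist())
    return mapping


#: Rank of each archetype along the A -> E signal flow.
CLUSTER_RANK = {letter: i + 1 for i, letter in enumerate(ARCHETYPE_LETTERS)}
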