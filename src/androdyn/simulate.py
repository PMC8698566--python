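"""Synthetic inputs with the statistical structure the analysis assumes.

The generators emulate a 5-time-point (0, 5, 15, 30, 60 min), 3-replicate,
two-condition TMT-style experiment over ~4,500 proteins with five planted
temporal archetypes plus a white-noise class, archetype-biased annotations,
a PPI network with planted excess interaction between chosen cluster pairs,
cluster-designated gene-set concepts, and multi-dataset expression cohorts
with planted up/down markers.  Every generator is a pure function of its
parameters and seed.

Raw-scale profile construction inverts the preprocessing chain (scale the
standardized archetype to a log2 amplitude, exponentiate, re-apply per-sample
scale factors and per-protein baselines) so the preprocessing stage is
exercised rather than bypassed.  The default mix keeps a null/noise fraction
whose per-column median ratio is ~1; that anchors the per-sample median
centering, which would otherwise absorb any signal shared by a majority of
proteins.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field as dc_field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import AnnotationTable, GeneSetCollection, RatioTable, TIME_POINTS
from .markers import ExpressionDataset

ARCHETYPE_NAMES = ("A", "B", "C", "D", "E")

#: Piecewise-linear temporal templates (raw shape, z-scored on definition).
#: A: peaks 5-15 min then declines; B: elevated 5-30 min; C: bimodal (both
#: ends elevated); D: rises from 30 min; E: monotone rise to a 60-min max.
#: The raw values are free design constants; they are chosen so the five
#: z-scored templates are mutually well separated (pairwise correlation
#: <= 0.4) while keeping the qualitative shapes above.
_RAW_TEMPLATES = {
    "A": (0.0, 1.6, 0.4, -0.8, -1.2),
    "B": (-1.4, 0.5, 0.9, 0.9, -0.9),
    "C": (1.0, 0.6, -1.5, -0.4, 0.9),
    "D": (-0.7, -1.0, -0.1, 1.5, 0.3),
    "E": (-0.7, -0.6, -0.6, 0.0, 1.9),
}


def _zscore(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return (v - v.mean()) / v.std(ddof=1)


ARCHETYPES: dict[str, np.ndarray] = {
    name: _zscore(np.array(raw)) for name, raw in _RAW_TEMPLATES.items()
}

#: Default composition: five balanced archetypes plus a fuzzy/noise class,
#: emulating a ~3/4 retained fraction after the membership filter.
DEFAULT_MIX = {"A": 0.16, "B": 0.16, "C": 0.16, "D": 0.16, "E": 0.16,
               "noise": 0.20}

#: Baseline compartment frequencies of the annotated proteome
#: (extracellular 3.6%, plasma membrane 10.2%, cytoplasm 56.6%,
#: nucleus 29.5%; a small unknown mass is added and renormalized).
BASE_COMPARTMENT_P = {
    "extracellular space": 0.034,
    "plasma membrane": 0.097,
    "cytoplasm": 0.539,
    "nucleus": 0.28,
    "other/unknown": 0.05,
}

#: Baseline molecular-type frequencies (enzyme-heavy, receptor classes rare).
BASE_TYPE_P = {
    "transcription regulator": 0.10,
    "ligand-dependent nuclear receptor": 0.01,
    "translation regulator": 0.02,
    "phosphatase": 0.03,
    "peptidase": 0.04,
    "kinase": 0.06,
    "enzyme": 0.25,
    "transporter": 0.06,
    "ion channel": 0.02,
    "transmembrane receptor": 0.03,
    "G-protein coupled receptor": 0.01,
    "growth factor": 0.01,
    "cytokine": 0.01,
    "other/unknown": 0.35,
}

#: Planted annotation biases: archetype -> (compartment(s), molecular types).
PLANTED_BIAS = {
    "A": {"compartment": ("plasma membrane",),
          "molecular_type": ("transporter", "transmembrane receptor")},
    "C": {"compartment": ("nucleus",), "molecular_type": ()},
    "D": {"compartment": ("nucleus",), "molecular_type": ()},
    "E": {"compartment": ("nucleus",),
          "molecular_type": ("transcription regulator",
                             "translation regulator")},
}

#: Cluster pairs carrying planted excess PPI edges by default.
DEFAULT_PAIR_EXCESS = {("C", "E"): 5.0, ("D", "E"): 5.0, ("C", "D"): 5.0}


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated scenario, for recovery tests."""

    archetypes: pd.Series                    # protein -> A..E or 'noise'
    annotation_bias: dict = dc_field(default_factory=dict)
    bias_odds: float | None = None
    pair_excess: dict = dc_field(default_factory=dict)
    hubs: dict = dc_field(default_factory=dict)
    marker_genes: pd.DataFrame | None = None  # gene, direction, datasets
    concept_clusters: dict = dc_field(default_factory=dict)
    params: dict = dc_field(default_factory=dict)

    def members(self, archetype: str) -> pd.Index:
        return self.archetypes.index[self.archetypes == archetype]

    def to_json(self, path) -> None:
        payload = {
            "archetypes": self.archetypes.to_dict(),
            "annotation_bias": {k: {kk: list(vv) for kk, vv in v.items()}
                                for k, v in self.annotation_bias.items()},
            "bias_odds": self.bias_odds,
            "pair_excess": {"/".join(k): v
                            for k, v in self.pair_excess.items()},
            "hubs": self.hubs,
            "marker_genes": (self.marker_genes.to_dict(orient="records")
                             if self.marker_genes is not None else None),
            "concept_clusters": self.concept_clusters,
            "params": self.params,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Temporal profiles
# ---------------------------------------------------------------------------

def generate_profiles(
    n_proteins: int = 4500,
    archetype_mix: dict[str, float] | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
    amplitude: float = 0.3,
    rep_noise_sd: float = 0.08,
    sample_scale_sd: float = 0.1,
    frac_low_peptide: float = 0.03,
    frac_missing: float = 0.02,
) -> tuple[RatioTable, SyntheticTruth]:
    """Simulate the raw treated/vehicle quantification table.

    Each archetype protein's averaged log2 ratio profile is
    ``amplitude * (archetype + N(0, noise_sd^2))`` plus a per-protein offset;
    noise-class proteins get white-noise profiles.  Per-replicate scatter
    (sd ``rep_noise_sd``, centered within each protein/time so the replicate
    mean is exact) and per-sample lognormal scale factors
    (sd ``sample_scale_sd``, absorbed by median centering) are layered on
    top, then treated = vehicle * ratio on a lognormal intensity baseline.
    A small fraction of proteins is planted with one unique peptide or one
    missing cell to exercise the quantification filters.
    """
    if n_proteins < 50:
        raise ParameterError("n_proteins must be >= 50")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    mix = dict(DEFAULT_MIX if archetype_mix is None else archetype_mix)
    unknown = set(mix) - set(ARCHETYPE_NAMES) - {"noise"}
    if unknown:
        raise ParameterError(f"unknown archetypes in mix: {sorted(unknown)}")
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-8:
        raise ParameterError(f"archetype_mix sums to {total}, expected 1")

    rng = np.random.default_rng(seed)
    classes = sorted(mix)
    probs = np.array([mix[c] for c in classes])
    arche = [str(a) for a in rng.choice(classes, size=n_proteins, p=probs)]
    ids = pd.Index([f"P{i:05d}" for i in range(n_proteins)], name="protein_id")

    D = len(TIME_POINTS)
    profiles = np.empty((n_proteins, D))
    for i, a in enumerate(arche):
        if a == "noise":
            profiles[i] = rng.normal(0.0, 1.0, size=D)
        else:
            profiles[i] = ARCHETYPES[a] + rng.normal(0.0, noise_sd, size=D)
    offsets = rng.normal(0.0, 0.05, size=n_proteins)
    log2_mean = amplitude * profiles + offsets[:, None]

    n_rep = 3
    delta = rng.normal(0.0, rep_noise_sd, size=(n_proteins, D, n_rep))
    delta -= delta.mean(axis=2, keepdims=True)  # replicate mean is exact
    log2_rep = log2_mean[:, :, None] + delta
    ratio = 2.0 ** log2_rep  # protein x time x replicate

    scale = 2.0 ** rng.normal(0.0, sample_scale_sd, size=(D, n_rep))
    ratio = ratio * scale[None, :, :]

    base = 2.0 ** rng.normal(14.0, 1.5, size=n_proteins)
    veh_noise = 2.0 ** rng.normal(0.0, 0.1, size=(n_proteins, D, n_rep))
    vehicle = base[:, None, None] * veh_noise
    treated = vehicle * ratio

    cols = pd.MultiIndex.from_tuples(
        [(cond, t, r + 1) for cond in ("treated", "vehicle")
         for t in TIME_POINTS for r in range(n_rep)],
        names=["condition", "time", "replicate"])
    data = np.concatenate(
        [treated.reshape(n_proteins, -1), vehicle.reshape(n_proteins, -1)],
        axis=1)
    values = pd.DataFrame(data, index=ids, columns=cols)

    peptides = pd.Series(rng.poisson(8, size=n_proteins) + 2, index=ids)
    n_low = int(round(frac_low_peptide * n_proteins))
    n_miss = int(round(frac_missing * n_proteins))
    flawed = rng.choice(n_proteins, size=n_low + n_miss, replace=False)
    low_idx, miss_idx = flawed[:n_low], flawed[n_low:]
    peptides.iloc[low_idx] = 1
    for i in miss_idx:
        j = int(rng.integers(len(cols)))
        values.iloc[i, j] = np.nan
    arch_series = pd.Series(arche, index=ids, name="archetype")
    arch_series.iloc[flawed] = "dropped"  # filtered out before clustering

    truth = SyntheticTruth(
        archetypes=arch_series,
        params={"n_proteins": n_proteins, "noise_sd": noise_sd,
                "amplitude": amplitude, "rep_noise_sd": rep_noise_sd,
                "sample_scale_sd": sample_scale_sd, "seed": seed,
                "mix": mix})
    return RatioTable(values=values, unique_peptides=peptides), truth


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def generate_annotations(truth: SyntheticTruth, bias_odds: float = 8.0,
                         seed: int = 0) -> AnnotationTable:
    """Draw compartment / molecular type with archetype-biased odds.

    Categories come from baseline multinomials whose odds are multiplied by
    ``bias_odds`` for the planted (archetype, category) pairs: A toward the
    plasma membrane with transporters/transmembrane receptors, C and D
    toward the nucleus, E toward the nucleus with transcription/translation
    regulators.  ``bias_odds=1`` is the null (no planted signal).
    """
    if bias_odds < 1:
        raise ParameterError("bias_odds must be >= 1")
    rng = np.random.default_rng(seed)
    rows = {}
    comp_cats = list(BASE_COMPARTMENT_P)
    type_cats = list(BASE_TYPE_P)
    comp_base = np.array([BASE_COMPARTMENT_P[c] for c in comp_cats])
    type_base = np.array([BASE_TYPE_P[c] for c in type_cats])
    for pid, a in truth.archetypes.items():
        bias = PLANTED_BIAS.get(a, {})
        cp = comp_base.copy()
        for cat in bias.get("compartment", ()):
            cp[comp_cats.index(cat)] *= bias_odds
        tp = type_base.copy()
        for cat in bias.get("molecular_type", ()):
            tp[type_cats.index(cat)] *= bias_odds
        rows[pid] = (str(rng.choice(comp_cats, p=cp / cp.sum())),
                     str(rng.choice(type_cats, p=tp / tp.sum())))
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=["compartment", "molecular_type"])
    table.index.name = "protein_id"
    truth.annotation_bias = {k: {kk: tuple(vv) for kk, vv in v.items()}
                             for k, v in PLANTED_BIAS.items()}
    truth.bias_odds = bias_odds
    return AnnotationTable(table)


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------

def generate_ppi(
    truth_or_labels,
    base_rate: float = 0.002,
    pair_excess: dict[tuple[str, str], float] | None = None,
    hub_spec: dict[str, int] | None = None,
    seed: int = 0,
) -> nx.Graph:
    """Erdos-Renyi-like PPI graph with planted cluster-pair excess edges.

    Edge probability between two proteins is ``base_rate`` multiplied by the
    ``pair_excess`` factor of their (unordered) cluster pair.  ``hub_spec``
    wires named extra proteins (e.g. a synthetic EGFR) to an exact number of
    uniformly chosen partners.  Accepts a :class:`SyntheticTruth` or any
    protein -> label Series.
    """
    labels = (truth_or_labels.archetypes
              if isinstance(truth_or_labels, SyntheticTruth)
              else truth_or_labels)
    labels = labels[labels != "dropped"]
    if pair_excess is None:
        pair_excess = {}
    pair_excess = {tuple(sorted(k)): v for k, v in pair_excess.items()}
    rng = np.random.default_rng(seed)
    graph = nx.Graph()
    graph.add_nodes_from(labels.index)
    by_class: dict[str, np.ndarray] = {
        c: labels.index[labels == c].to_numpy()
        for c in sorted(labels.unique())}
    for c1, c2 in itertools.combinations_with_replacement(
            sorted(by_class), 2):
        nodes1, nodes2 = by_class[c1], by_class[c2]
        if c1 == c2:
            n_pairs = len(nodes1) * (len(nodes1) - 1) // 2
        else:
            n_pairs = len(nodes1) * len(nodes2)
        if n_pairs == 0:
            continue
        p = min(base_rate * pair_excess.get((c1, c2), 1.0), 1.0)
        m = rng.binomial(n_pairs, p)
        if m == 0:
            continue
        flat = rng.choice(n_pairs, size=m, replace=False)
        if c1 == c2:
            # map flat index to (i, j), i < j
            i = (np.floor((2 * len(nodes1) - 1
                           - np.sqrt((2 * len(nodes1) - 1) ** 2
                                     - 8 * flat)) / 2)).astype(int)
            j = (flat - i * (2 * len(nodes1) - i - 1) // 2 + i + 1).astype(int)
            graph.add_edges_from(zip(nodes1[i], nodes1[j]))
        else:
            i, j = np.divmod(flat, len(nodes2))
            graph.add_edges_from(zip(nodes1[i], nodes2[j]))
    if hub_spec:
        pool = labels.index.to_numpy()
        for hub, degree in hub_spec.items():
            if degree > len(pool):
                raise ParameterError(
                    f"hub {hub!r} degree {degree} exceeds {len(pool)} proteins")
            partners = rng.choice(pool[pool != hub], size=degree,
                                  replace=False)
            graph.add_edges_from((hub, p) for p in partners)
    if isinstance(truth_or_labels, SyntheticTruth):
        truth_or_labels.pair_excess = dict(pair_excess)
        truth_or_labels.hubs = dict(hub_spec or {})
    return graph


# ---------------------------------------------------------------------------
# Marker datasets
# ---------------------------------------------------------------------------

def generate_marker_datasets(
    n_datasets: int = 6,
    n_genes: int = 2000,
    planted: dict[str, str] | None = None,
    effect: float = 2.0,
    n_per_group: int = 20,
    seed: int = 0,
    genes: list[str] | None = None,
    min_planted_datasets: int = 2,
    truth: SyntheticTruth | None = None,
    n_planted: int = 100,
) -> list[ExpressionDataset]:
    """Gaussian two-group expression cohorts with planted markers.

    ``planted`` maps gene -> direction ("up"/"down"); when omitted,
    ``n_planted`` genes are drawn (from ``truth``'s archetype proteins when
    supplied, so markers intersect the clusters) with random directions.
    Each planted gene is shifted by ``effect`` standardized units in a
    random subset of at least ``min_planted_datasets`` datasets; all other
    gene/dataset combinations are null.  ``effect=0`` is the null scenario.
    """
    rng = np.random.default_rng(seed)
    if genes is None:
        if truth is not None:
            pool = truth.archetypes.index[
                truth.archetypes.isin(ARCHETYPE_NAMES)]
            genes = list(pool[:n_genes])
        else:
            genes = [f"G{i:05d}" for i in range(n_genes)]
    n_genes = len(genes)
    if planted is None:
        chosen = rng.choice(n_genes, size=min(n_planted, n_genes),
                            replace=False)
        planted = {genes[i]: ("up" if rng.random() < 0.5 else "down")
                   for i in chosen}
    gene_pos = {g: i for i, g in enumerate(genes)}
    active: dict[str, np.ndarray] = {}
    for g in planted:
        k = int(rng.integers(min_planted_datasets, n_datasets + 1))
        active[g] = rng.choice(n_datasets, size=k, replace=False)

    datasets = []
    for d in range(n_datasets):
        X = rng.normal(0.0, 1.0, size=(n_genes, 2 * n_per_group))
        for g, direction in planted.items():
            if d in active[g]:
                shift = effect if direction == "up" else -effect
                X[gene_pos[g], :n_per_group] += shift
        cols = ([f"case_{i}" for i in range(n_per_group)]
                + [f"ctrl_{i}" for i in range(n_per_group)])
        groups = pd.Series(["case"] * n_per_group + ["control"] * n_per_group,
                           index=cols)
        values = pd.DataFrame(X, index=pd.Index(genes, name="gene"),
                              columns=cols)
        datasets.append(ExpressionDataset(values=values, groups=groups,
                                          dataset_id=f"DS{d + 1}"))
    marker_truth = pd.DataFrame(
        [{"gene": g, "direction": direction,
          "n_datasets": len(active[g])}
         for g, direction in sorted(planted.items())])
    if truth is not None:
        truth.marker_genes = marker_truth
    else:
        datasets[0].values.attrs["planted"] = marker_truth
    return datasets


def generate_paired_dataset(
    n_genes: int = 2000,
    planted: dict[str, str] | None = None,
    effect: float = 1.5,
    n_pairs: int = 52,
    seed: int = 0,
    genes: list[str] | None = None,
    n_planted: int = 60,
) -> ExpressionDataset:
    """Matched tumor/normal cohort with planted per-pair shifts."""
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = [f"G{i:05d}" for i in range(n_genes)]
    n_genes = len(genes)
    if planted is None:
        chosen = rng.choice(n_genes, size=min(n_planted, n_genes),
                            replace=False)
        planted = {genes[i]: ("up" if rng.random() < 0.5 else "down")
                   for i in chosen}
    gene_pos = {g: i for i, g in enumerate(genes)}
    tumor = rng.normal(0.0, 1.0, size=(n_genes, n_pairs))
    normal = rng.normal(0.0, 1.0, size=(n_genes, n_pairs))
    for g, direction in planted.items():
        shift = effect if direction == "up" else -effect
        tumor[gene_pos[g]] += shift
    cols = [f"T{i}" for i in range(n_pairs)] + [f"N{i}" for i in range(n_pairs)]
    values = pd.DataFrame(np.concatenate([tumor, normal], axis=1),
                          index=pd.Index(genes, name="gene"), columns=cols)
    groups = pd.Series(["case"] * n_pairs + ["control"] * n_pairs, index=cols)
    pairs = pd.Series([f"pair{i}" for i in range(n_pairs)] * 2, index=cols)
    ds = ExpressionDataset(values=values, groups=groups, dataset_id="paired",
                           pairs=pairs)
    ds.values.attrs["planted"] = pd.DataFrame(
        [{"gene": g, "direction": d} for g, d in sorted(planted.items())])
    return ds


# ---------------------------------------------------------------------------
# Concepts
# ---------------------------------------------------------------------------

def generate_concepts(truth: SyntheticTruth, n_concepts: int = 15,
                      overlap_odds: float = 10.0, seed: int = 0,
                      base_rate: float = 0.04) -> GeneSetCollection:
    """Gene-set concepts with inflated membership odds for one cluster each.

    Every concept designates a cluster (round-robin over A-E); membership
    probability is ``base_rate`` for all proteins, multiplied by
    ``overlap_odds`` for the designated cluster's members.
    ``overlap_odds=1`` is the null.
    """
    if overlap_odds < 1:
        raise ParameterError("overlap_odds must be >= 1")
    rng = np.random.default_rng(seed)
    labels = truth.archetypes[truth.archetypes.isin(ARCHETYPE_NAMES)]
    sets: dict[str, frozenset] = {}
    sources: dict[str, str] = {}
    designated: dict[str, str] = {}
    for i in range(n_concepts):
        cluster = ARCHETYPE_NAMES[i % len(ARCHETYPE_NAMES)]
        p = np.where(labels == cluster,
                     min(base_rate * overlap_odds, 1.0), base_rate)
        members = labels.index[rng.random(len(labels)) < p]
        if len(members) == 0:
            continue
        name = f"concept_{i + 1:02d}"
        sets[name] = frozenset(members)
        sources[name] = "synthetic"
        designated[name] = cluster
    truth.concept_clusters = designated
    return GeneSetCollection(sets=sets, sources=sources)
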