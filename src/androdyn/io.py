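"""Readers and writers for the pipeline's external formats.

Tables travel as TSV, interaction networks as BioGRID TAB 3.0 / MITAB (input)
and GraphML / SIF (output, Cytoscape-compatible), gene sets as GMT.  Protein
identifiers are uppercase gene symbols throughout; all joins between the
proteome table, the annotation table, the interaction network and marker gene
lists are case-insensitive on the symbol.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError, IngestionError

log = logging.getLogger("androdyn")

TIME_POINTS: tuple[int, ...] = (0, 5, 15, 30, 60)
CONDITIONS: tuple[str, str] = ("treated", "vehicle")
REPLICATES: tuple[int, ...] = (1, 2, 3)

COMPARTMENTS: tuple[str, ...] = (
    "extracellular space",
    "plasma membrane",
    "cytoplasm",
    "nucleus",
    "other/unknown",
)

MOLECULAR_TYPES: tuple[str, ...] = (
    "transcription regulator",
    "ligand-dependent nuclear receptor",
    "translation regulator",
    "phosphatase",
    "peptidase",
    "kinase",
    "enzyme",
    "transporter",
    "ion channel",
    "transmembrane receptor",
    "G-protein coupled receptor",
    "growth factor",
    "cytokine",
    "other/unknown",
)

_COLUMN_RE = re.compile(r"^(?P<cond>[A-Za-z]+)_t(?P<time>\d+)_r(?P<rep>\d+)$")


def normalize_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


# ---------------------------------------------------------------------------
# RatioTable
# ---------------------------------------------------------------------------

@dataclass
class RatioTable:
    """Per-protein raw quantification across condition x time x replicate.

    ``values`` has the protein symbol as index and a 3-level column
    MultiIndex (condition, time, replicate).  Missing entries are NaN; all
    present values are finite and positive (intensity/ratio scale).
    """

    values: pd.DataFrame
    unique_peptides: pd.Series

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise IngestionError(f"duplicate protein_id {dup!r}")
        vals = self.values.to_numpy(dtype=float)
        present = ~np.isnan(vals)
        if not np.all(np.isfinite(vals[present]) & (vals[present] > 0)):
            raise IngestionError("RatioTable values must be finite and > 0")
        times = sorted({t for _, t, _ in self.values.columns})
        self.values = self.values.sort_index(
            axis=1, level=[0, 1, 2], sort_remaining=True
        )
        self.times = tuple(times)

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    def __len__(self) -> int:
        return len(self.values)


def default_layout(columns) -> dict[str, tuple[str, int, int]]:
    """Infer the (condition, time, replicate) mapping from canonical
    ``<condition>_t<time>_r<rep>`` column names."""
    layout = {}
    for col in columns:
        m = _COLUMN_RE.match(col)
        if m:
            layout[col] = (m.group("cond"), int(m.group("time")), int(m.group("rep")))
    return layout


def read_ratio_table(path: str | Path, layout: dict | None = None) -> RatioTable:
    """Read a TSV quantification table.

    ``layout`` maps value-column names to (condition, time, replicate);
    if omitted it is inferred from canonical column names.  Rows carrying a
    non-positive or unparsable value are dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if "protein_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'protein_id'")
    if "unique_peptides" not in df.columns:
        raise FormatError(f"{path}: missing required column 'unique_peptides'")
    if layout is None:
        layout = default_layout(df.columns)
    if not layout:
        raise FormatError(f"{path}: no value columns recognised")
    missing = [c for c in layout if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: layout columns absent from file: {missing}")

    ids = df["protein_id"].map(normalize_symbol)
    dup = ids[ids.duplicated()]
    if len(dup):
        raise IngestionError(f"duplicate protein_id {dup.iloc[0]!r} in {path}")

    vals = df[list(layout)].apply(pd.to_numeric, errors="coerce")
    bad = ((vals <= 0) | ~np.isfinite(vals)) & df[list(layout)].notna().to_numpy()
    bad_rows = bad.any(axis=1)
    if bad_rows.any():
        log.warning("read_ratio_table: dropped %d rows with non-positive or "
                    "unparsable values", int(bad_rows.sum()))
    keep = ~bad_rows
    vals = vals.loc[keep]
    vals.index = ids[keep]
    vals.columns = pd.MultiIndex.from_tuples(
        [layout[c] for c in vals.columns], names=["condition", "time", "replicate"]
    )
    peptides = pd.to_numeric(df.loc[keep, "unique_peptides"]).astype(int)
    peptides.index = ids[keep]
    return RatioTable(values=vals, unique_peptides=peptides)


def write_ratio_table(table: RatioTable, path: str | Path) -> None:
    flat = table.values.copy()
    flat.columns = [f"{c}_t{t}_r{r}" for c, t, r in flat.columns]
    out = pd.concat(
        [table.unique_peptides.rename("unique_peptides"), flat], axis=1
    )
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# AnnotationTable
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTable:
    """One subcellular compartment and one molecular type per protein."""

    table: pd.DataFrame  # index protein_id; columns compartment, molecular_type

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise IngestionError("duplicate protein_id in annotations")
        bad_c = set(self.table["compartment"]) - set(COMPARTMENTS)
        if bad_c:
            raise IngestionError(f"unknown compartments {sorted(bad_c)}")
        bad_t = set(self.table["molecular_type"]) - set(MOLECULAR_TYPES)
        if bad_t:
            raise IngestionError(f"unknown molecular types {sorted(bad_t)}")

    @property
    def compartment(self) -> pd.Series:
        return self.table["compartment"]

    @property
    def molecular_type(self) -> pd.Series:
        return self.table["molecular_type"]

    def __len__(self) -> int:
        return len(self.table)


def read_annotations(path: str | Path) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("protein_id", "compartment", "molecular_type"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    df["protein_id"] = df["protein_id"].map(normalize_symbol)
    return AnnotationTable(df.set_index("protein_id")[["compartment", "molecular_type"]])


def write_annotations(ann: AnnotationTable, path: str | Path) -> None:
    out = ann.table.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# BioGRID / MITAB interaction networks
# ---------------------------------------------------------------------------

DEFAULT_ALLOWED_SYSTEMS = frozenset({"direct interaction", "physical association"})

# PSI-MI names vs BioGRID experimental-system vocabulary.
_SYSTEM_ALIASES = {
    "direct interaction": {"direct interaction", "direct"},
    "physical association": {"physical association", "physical"},
}

_MI_NAME_RE = re.compile(r'psi-mi:"?MI:\d+"?\((?P<name>[^)]+)\)')
_LOCUSLINK_RE = re.compile(r"entrez gene/locuslink:([^|(\t]+)")


def _system_allowed(tokens: set[str], allowed: frozenset[str]) -> bool:
    tokens = {t.strip().lower() for t in tokens if t}
    for want in allowed:
        names = _SYSTEM_ALIASES.get(want.lower(), {want.lower()})
        if tokens & names:
            return True
    return False


def read_biogrid(
    path: str | Path,
    allowed_systems: frozenset[str] | set[str] = DEFAULT_ALLOWED_SYSTEMS,
    organism: int | None = 9606,
) -> nx.Graph:
    """Parse a BioGRID TAB 3.0 or MITAB export into an undirected simple graph.

    Only rows whose experimental system (or PSI-MI interaction type) is in
    ``allowed_systems`` are retained; self-loops are removed and duplicate
    edges collapsed.  When organism columns are present, rows are restricted
    to ``organism`` (human by default).  A plain 3-column
    (symbol_a, symbol_b, system) TSV is also accepted.
    """
    allowed = frozenset(allowed_systems)
    head = pd.read_csv(path, sep="\t", nrows=0)
    cols = list(head.columns)
    lower = {c.lower().lstrip("#"): c for c in cols}

    if "official symbol interactor a" in lower:  # TAB 3.0
        df = pd.read_csv(path, sep="\t", dtype=str, low_memory=False)
        a_col = lower["official symbol interactor a"]
        b_col = lower["official symbol interactor b"]
        sys_cols = [lower[c] for c in
                    ("experimental system", "experimental system type")
                    if c in lower]
        org_cols = [lower[c] for c in
                    ("organism id interactor a", "organism id interactor b")
                    if c in lower]
    elif "id interactor a" in lower or "ids interactor a" in lower \
            or "id(s) interactor a" in lower:  # MITAB
        df = pd.read_csv(path, sep="\t", dtype=str, low_memory=False)
        df.columns = [c.lstrip("#") for c in df.columns]
        lower = {c.lower(): c for c in df.columns}

        def mitab_symbols(row_fields: pd.Series) -> pd.Series:
            return row_fields.map(
                lambda s: (_LOCUSLINK_RE.search(s or "").group(1).strip()
                           if s and _LOCUSLINK_RE.search(s) else None)
            )

        alt_a = lower.get("alt ids interactor a") or lower.get("alt id(s) interactor a")
        alt_b = lower.get("alt ids interactor b") or lower.get("alt id(s) interactor b")
        if alt_a is None or alt_b is None:
            raise FormatError(f"{path}: MITAB without alt-id columns; "
                              f"detected columns {list(df.columns)}")
        df["_sym_a"] = mitab_symbols(df[alt_a])
        df["_sym_b"] = mitab_symbols(df[alt_b])
        it_col = lower.get("interaction types") or lower.get("interaction type(s)")
        if it_col is None:
            raise FormatError(f"{path}: MITAB without interaction-type column")
        df["_system"] = df[it_col].map(
            lambda s: (_MI_NAME_RE.search(s).group("name") if s and
                       _MI_NAME_RE.search(s) else s))
        a_col, b_col = "_sym_a", "_sym_b"
        sys_cols = ["_system"]
        org_cols = [lower[c] for c in ("taxid interactor a", "taxid interactor b")
                    if c in lower]
    elif {"symbol_a", "symbol_b", "system"} <= set(lower):  # generic edge list
        df = pd.read_csv(path, sep="\t", dtype=str)
        a_col, b_col = lower["symbol_a"], lower["symbol_b"]
        sys_cols = [lower["system"]]
        org_cols = []
    else:
        raise FormatError(
            f"{path}: unknown interaction dialect; detected columns {cols}")

    graph = nx.Graph()
    n_rows = 0
    for _, row in df.iterrows():
        tokens = {str(row[c]) for c in sys_cols if pd.notna(row[c])}
        if not _system_allowed(tokens, allowed):
            continue
        if organism is not None and org_cols:
            orgs = {re.sub(r"[^\d-]", "", str(row[c])) for c in org_cols}
            if orgs - {str(organism)}:
                continue
        a, b = row[a_col], row[b_col]
        if pd.isna(a) or pd.isna(b):
            continue
        a, b = normalize_symbol(a), normalize_symbol(b)
        if a == b:
            continue  # self-loop
        system = next(iter(tokens), "")
        if graph.has_edge(a, b):
            graph[a][b]["systems"] = graph[a][b]["systems"] | {system}
        else:
            graph.add_edge(a, b, systems={system})
        n_rows += 1
    log.info("read_biogrid: %d rows kept, %d unique edges over %d proteins",
             n_rows, graph.number_of_edges(), graph.number_of_nodes())
    return graph


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets with a free-form source tag per concept."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    sources: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise IngestionError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, frozenset[str]] = {}
    sources: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs "
                                  "name, description, >=1 member")
            name, desc, *members = parts
            members = [normalize_symbol(m) for m in members if m.strip()]
            if not members:
                log.warning("read_gmt: skipping empty gene set %r", name)
                continue
            if name in sets:
                raise IngestionError(f"duplicate gene set name {name!r}")
            sets[name] = frozenset(members)
            sources[name] = desc
    return GeneSetCollection(sets=sets, sources=sources)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            desc = collection.sources.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------

def write_network(
    network: nx.Graph,
    path: str | Path,
    assignment=None,
    fmt: str = "graphml",
) -> None:
    """Export a network for Cytoscape as GraphML or SIF.

    When a cluster assignment is supplied its labels are attached as a node
    attribute before writing.
    """
    graph = network.copy()
    if assignment is not None:
        labels = assignment.labels if hasattr(assignment, "labels") else assignment
        nx.set_node_attributes(
            graph, {n: labels[n] for n in graph.nodes if n in labels}, "cluster")
    # GraphML cannot serialise sets or numpy scalars
    def _clean(data):
        for key, val in list(data.items()):
            if isinstance(val, (set, frozenset)):
                data[key] = "|".join(sorted(val))
            elif isinstance(val, np.generic):
                data[key] = val.item()

    for _, _, data in graph.edges(data=True):
        _clean(data)
    for _, data in graph.nodes(data=True):
        _clean(data)
    fmt = fmt.lower()
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for a, b in sorted(graph.edges()):
                fh.write(f"{a}\tpp\t{b}\n")
            for n in sorted(nx.isolates(graph)):
                fh.write(f"{n}\n")
    else:
        raise FormatError(f"unknown network format {fmt!r}")


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)
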