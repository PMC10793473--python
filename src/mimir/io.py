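"""Readers/writers for the external formats the toolkit touches, plus count
normalization and the shared primary data containers.

Matrices are oriented genes x cells everywhere. Gene and protein identifiers
are treated as opaque strings; any protein-to-gene mapping must happen
upstream of this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import obonet
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

#: Per-cell metadata columns recognised by the toolkit.
CELL_META_COLUMNS = ("pseudotime", "stage", "cell_type", "condition", "batch")

#: OBO relationship types with a defined semantic weight.
SUPPORTED_RELATIONS = ("is_a", "part_of")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class CountMatrix:
    """UMI count table (genes x cells) with per-cell metadata.

    ``counts`` holds nonnegative integers; ``cell_meta`` is indexed by cell id
    and carries pseudotime, stage, cell_type, condition and batch columns
    (missing optional columns are filled with NA).
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: np.ndarray
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ParseError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ParseError("duplicate cell identifiers")
        if np.any(self.counts < 0):
            raise ParseError("negative counts")
        for col in CELL_META_COLUMNS:
            if col not in self.cell_meta.columns:
                self.cell_meta[col] = pd.NA
        self.cell_meta = self.cell_meta.loc[self.cell_ids, list(CELL_META_COLUMNS)]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present") from None


@dataclass
class NormalizedMatrix:
    """Library-size normalized, log2-transformed expression (genes x cells).

    Each cell's counts are scaled to sum to ``scale_total`` before the
    ``log2(x + 1)`` transform, so a zero count maps to exactly 0.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray
    cell_meta: pd.DataFrame
    scale_total: int = 15000

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present") from None

    def subset_cells(self, cell_ids: list[str]) -> "NormalizedMatrix":
        idx = [self.cell_ids.index(c) for c in cell_ids]
        return NormalizedMatrix(
            gene_ids=list(self.gene_ids),
            cell_ids=list(cell_ids),
            values=self.values[:, idx],
            cell_meta=self.cell_meta.loc[cell_ids],
            scale_total=self.scale_total,
        )


@dataclass
class OntologyDAG:
    """Directed acyclic graph of annotation terms.

    ``graph`` stores child -> parent edges, each labelled with a relation in
    :data:`SUPPORTED_RELATIONS`. Obsolete terms never appear.
    """

    graph: nx.DiGraph
    names: dict[str, str] = field(default_factory=dict)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def parents(self, term: str) -> list[tuple[str, str]]:
        """(parent, relation) pairs for ``term``."""
        return [(p, self.graph.edges[term, p]["relation"]) for p in self.graph.successors(term)]

    def children(self, term: str) -> list[tuple[str, str]]:
        return [(c, self.graph.edges[c, term]["relation"]) for c in self.graph.predecessors(term)]

    def roots(self) -> set[str]:
        return {t for t in self.graph.nodes if self.graph.out_degree(t) == 0}

    def __contains__(self, term: str) -> bool:
        return term in self.graph


@dataclass
class AnnotationMap:
    """Gene -> term-set annotations for one database namespace."""

    database_name: str
    gene_to_terms: dict[str, frozenset[str]]

    def terms_for(self, gene: str) -> frozenset[str]:
        return self.gene_to_terms.get(gene, frozenset())

    def validate_against(self, dag: OntologyDAG) -> None:
        unknown = {t for ts in self.gene_to_terms.values() for t in ts} - dag.terms
        if unknown:
            raise ValueError(
                f"annotation map {self.database_name!r} references unknown terms: "
                f"{sorted(unknown)[:5]}"
            )


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class EvidenceChannels:
    """Per gene pair, named association scores in [0, 1] plus the fixed prior.

    Pair keys are unordered; a missing channel for a pair means that source
    carries no evidence (distinct from a zero score). Backed by a DataFrame
    indexed by the sorted (gene_a, gene_b) pair with one column per channel
    (NaN = missing).
    """

    table: pd.DataFrame
    prior: float = 0.41

    def __post_init__(self) -> None:
        if not 0 < self.prior < 1:
            raise ValueError(f"prior must lie in (0, 1), got {self.prior}")
        vals = self.table.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any((vals < 0) | (vals > 1)):
                raise ValueError("channel scores must lie in [0, 1]")

    @property
    def channel_names(self) -> list[str]:
        return list(self.table.columns)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(self.table.index)

    def channels_for(self, a: str, b: str) -> dict[str, float]:
        key = _pair_key(a, b)
        if key not in self.table.index:
            return {}
        row = self.table.loc[key]
        return {k: float(v) for k, v in row.items() if pd.notna(v)}

    @classmethod
    def from_records(
        cls,
        records: dict[tuple[str, str], dict[str, float]],
        prior: float = 0.41,
    ) -> "EvidenceChannels":
        keyed = {_pair_key(a, b): v for (a, b), v in records.items()}
        table = pd.DataFrame.from_dict(keyed, orient="index")
        table.index = pd.MultiIndex.from_tuples(
            table.index if len(table) else [], names=["gene_a", "gene_b"]
        )
        return cls(table=table, prior=prior)


@dataclass
class ModuleFile:
    """Ordered list of (module_id, annotation, member genes)."""

    modules: list[tuple[str, str, list[str]]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for mid, _, members in self.modules:
            if not members:
                raise ValueError(f"module {mid!r} is empty")
            dup = seen.intersection(members)
            if dup:
                raise ValueError(f"genes in more than one module: {sorted(dup)[:5]}")
            seen.update(members)

    def as_mapping(self) -> dict[str, str]:
        return {g: mid for mid, _, members in self.modules for g in members}


# ---------------------------------------------------------------------------
# Count matrices


def read_count_matrix(path, format: str, meta_path) -> CountMatrix:
    """Read a UMI count table plus per-cell metadata.

    ``format`` is ``"mtx_triplet"`` (MatrixMarket with ``<path>.genes.tsv`` /
    ``<path>.cells.tsv`` sidecars) or ``"dense_tsv"`` (gene rows x cell
    columns). Metadata is a TSV keyed by ``cell_id``; cells missing from it
    are rejected.
    """
    path = str(path)
    if format == "mtx_triplet":
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # scipy raises bare ValueError on bad headers
            raise ParseError(f"{path}: malformed MatrixMarket file ({exc})") from exc
        counts = np.asarray(scipy.sparse.coo_matrix(mat).todense())
        genes = _read_single_column(path + ".genes.tsv")
        cells = _read_single_column(path + ".cells.tsv")
        if counts.shape != (len(genes), len(cells)):
            raise ParseError(
                f"{path}: matrix is {counts.shape} but sidecars name "
                f"{len(genes)} genes x {len(cells)} cells"
            )
    elif format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        genes = [str(g) for g in df.index]
        cells = [str(c) for c in df.columns]
        counts = df.to_numpy()
    else:
        raise ValueError(f"unknown count format {format!r}")

    if not np.allclose(counts, np.round(counts)) or np.any(counts < 0):
        raise ParseError(f"{path}: counts must be nonnegative integers")
    counts = counts.astype(np.int64)

    meta = pd.read_csv(meta_path, sep="\t", dtype={"cell_id": str})
    if "cell_id" not in meta.columns:
        raise ParseError(f"{meta_path}: metadata must have a cell_id column")
    meta = meta.set_index("cell_id")
    if meta.index.duplicated().any():
        raise ParseError(f"{meta_path}: duplicate cell_id entries")
    missing = [c for c in cells if c not in meta.index]
    if missing:
        raise ParseError(f"{meta_path}: metadata missing cell ids {missing[:10]}")
    return CountMatrix(gene_ids=genes, cell_ids=cells, counts=counts, cell_meta=meta.loc[cells].copy())


def _read_single_column(path: str) -> list[str]:
    with open(path) as fh:
        items = [line.split("\t")[0].strip() for line in fh if line.strip()]
    if not items:
        raise ParseError(f"{path}: empty sidecar file")
    return items


def write_count_matrix(m: CountMatrix, path, format: str = "mtx_triplet") -> None:
    """Inverse of :func:`read_count_matrix` (metadata written to ``<path>.meta.tsv``)."""
    path = str(path)
    if format == "mtx_triplet":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(m.counts))
        with open(path + ".genes.tsv", "w") as fh:
            fh.write("".join(g + "\n" for g in m.gene_ids))
        with open(path + ".cells.tsv", "w") as fh:
            fh.write("".join(c + "\n" for c in m.cell_ids))
    elif format == "dense_tsv":
        pd.DataFrame(m.counts, index=m.gene_ids, columns=m.cell_ids).to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown count format {format!r}")
    m.cell_meta.rename_axis("cell_id").to_csv(path + ".meta.tsv", sep="\t")


def normalize_counts(m: CountMatrix, scale_total: int = 15000) -> NormalizedMatrix:
    """Scale each cell to ``scale_total`` counts, add 1, and take log2.

    values = log2(count * scale_total / cell_total + 1), so zero counts map to
    exactly 0 and, before the log, each cell's scaled counts sum to
    ``scale_total``.
    """
    totals = m.counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cells with zero total counts: {[m.cell_ids[i] for i in zero[:10]]}")
    values = np.log2(m.counts * (scale_total / totals) + 1.0)
    return NormalizedMatrix(
        gene_ids=list(m.gene_ids),
        cell_ids=list(m.cell_ids),
        values=values,
        cell_meta=m.cell_meta.copy(),
        scale_total=scale_total,
    )


# ---------------------------------------------------------------------------
# Ontologies and annotations


def read_obo(path) -> OntologyDAG:
    """Parse an OBO 1.2 ontology into an :class:`OntologyDAG`.

    Only ``is_a`` and ``part_of`` relations are retained (the semantic
    similarity measure defines weights only for these); other relationship
    types are skipped with a logged warning. Obsolete terms are excluded.
    A cyclic relation chain is an error.
    """
    multi = obonet.read_obo(str(path))  # skips obsolete stanzas by default
    graph = nx.DiGraph()
    names: dict[str, str] = {}
    for term, data in multi.nodes(data=True):
        graph.add_node(term)
        names[term] = data.get("name", term)
    skipped: set[str] = set()
    for child, parent, relation in multi.edges(keys=True):
        if relation not in SUPPORTED_RELATIONS:
            skipped.add(relation)
            continue
        graph.add_edge(child, parent, relation=relation)
    if skipped:
        logger.warning("ignored unsupported OBO relationship types: %s", sorted(skipped))
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ParseError(f"{path}: cyclic relation chain {[e[:2] for e in cycle]}")
    return OntologyDAG(graph=graph, names=names)


def read_annotations(path, database_name: str, format: str = "tsv") -> AnnotationMap:
    """Read gene -> term annotations from a two-column TSV or a GAF 2.x file.

    TSV columns are (gene, term); GAF uses columns 3 (symbol) and 5 (term id),
    skipping ``!`` comment lines and rows carrying a NOT qualifier.
    """
    gene_to_terms: dict[str, set[str]] = {}
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 2:
            raise ParseError(f"{path}: expected two tab-separated columns")
        for gene, term in zip(df.iloc[:, 0], df.iloc[:, 1]):
            gene_to_terms.setdefault(gene, set()).add(term)
    elif format == "gaf":
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                if line.startswith("!") or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 5:
                    raise ParseError(f"{path}:{i}: GAF row with fewer than 5 columns")
                if "NOT" in fields[3].split("|"):
                    continue
                gene_to_terms.setdefault(fields[2], set()).add(fields[4])
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    return AnnotationMap(
        database_name=database_name,
        gene_to_terms={g: frozenset(ts) for g, ts in gene_to_terms.items()},
    )


# ---------------------------------------------------------------------------
# Interaction evidence


def read_string_links(
    path,
    drop_channels: set[str] = frozenset({"database", "database_transferred"}),
    prior: float = 0.41,
) -> EvidenceChannels:
    """Read a STRING full-links style whitespace-delimited score table.

    The file convention stores integer scores 0-1000; they are divided by
    1000 into [0, 1] at parse time. Channels named in ``drop_channels`` are
    absent from the output. Pair keys are unordered; duplicate orientations of
    the same pair must agree.
    """
    df = pd.read_csv(path, sep=r"\s+")
    for col in ("protein1", "protein2"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    channels = [c for c in df.columns if c not in ("protein1", "protein2", "combined_score")]
    bad = df[channels].apply(lambda s: (s < 0) | (s > 1000)).any(axis=1)
    if bad.any():
        # +2 accounts for the header line and 1-based numbering
        raise ParseError(f"{path}: score outside 0-1000 at row {int(bad.idxmax()) + 2}")
    keep = [c for c in channels if c not in drop_channels]
    records: dict[tuple[str, str], dict[str, float]] = {}
    for row in df.itertuples(index=False):
        key = _pair_key(str(row.protein1), str(row.protein2))
        scores = {c: getattr(row, c) / 1000.0 for c in keep if getattr(row, c) > 0}
        prev = records.get(key)
        if prev is not None and prev != scores:
            raise ParseError(f"{path}: conflicting duplicate entries for pair {key}")
        records[key] = scores
    return EvidenceChannels.from_records(records, prior=prior)


# ---------------------------------------------------------------------------
# Module files


def write_modules(partition, path, format: str = "gmt") -> None:
    """Write a module partition as GMT (module_id, annotation, members...) or
    long-form TSV (gene, module). Empty annotations are written as "NA".
    """
    modules = _partition_to_modulefile(partition)
    path = str(path)
    if format == "gmt":
        with open(path, "w") as fh:
            for mid, ann, members in modules.modules:
                fh.write("\t".join([mid, ann or "NA", *members]) + "\n")
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("gene\tmodule\n")
            for mid, _, members in modules.modules:
                for g in members:
                    fh.write(f"{g}\t{mid}\n")
    else:
        raise ValueError(f"unknown module format {format!r}")


def read_modules(path, format: str = "gmt") -> ModuleFile:
    path = str(path)
    modules: list[tuple[str, str, list[str]]] = []
    if format == "gmt":
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 3:
                    raise ParseError(f"{path}:{i}: GMT row needs id, annotation, ≥1 member")
                modules.append((fields[0], fields[1], fields[2:]))
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for mid, group in df.groupby("module", sort=False):
            modules.append((str(mid), "NA", list(group["gene"])))
    else:
        raise ValueError(f"unknown module format {format!r}")
    return ModuleFile(modules=modules)


def _partition_to_modulefile(partition) -> ModuleFile:
    if isinstance(partition, ModuleFile):
        return partition
    if hasattr(partition, "assignments"):  # ModulePartition duck type
        mapping = partition.assignments
        annotations = getattr(partition, "annotations", {}) or {}
    elif isinstance(partition, dict):
        mapping, annotations = partition, {}
    else:
        raise TypeError(f"cannot serialise {type(partition).__name__} as modules")
    if not mapping:
        raise ValueError("empty partition")
    by_module: dict[str, list[str]] = {}
    for gene, mid in mapping.items():
        by_module.setdefault(str(mid), []).append(gene)
    return ModuleFile(
        modules=[
            (mid, annotations.get(mid, "NA"), sorted(members))
            for mid, members in sorted(by_module.items())
        ]
    )
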