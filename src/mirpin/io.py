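"""Readers and writers for the tabular formats the pipeline consumes.

Formats are deliberately plain: TSV expression matrices (features x samples,
``NA`` for missing), two-column target-prediction tables, PPI edge lists
(two-column TSV or three-column SIF), ontologies as an OBO subset or a
terms + child->parent edge TSV pair, and annotations as GMT. Gene identity
is the bare symbol string, case-sensitive; no alias resolution is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

NORMAL = "normal"
TUMOR = "tumor"
MISSING_TOKEN = "NA"


class FormatError(ValueError):
    """A file does not conform to its documented layout."""


class StructuralError(ValueError):
    """A parsed object violates a structural invariant (e.g. a cyclic ontology)."""


class UsageError(ValueError):
    """An operation was called with arguments outside its contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A features x samples abundance table.

    ``values`` is a pandas DataFrame indexed by feature id with sample-id
    columns. ``scale_hint`` records whether the stored numbers are linear
    abundances or log2 values; downstream statistics transform accordingly.
    Missing values are NaN.
    """

    values: pd.DataFrame
    scale_hint: str = "linear"

    def __post_init__(self) -> None:
        if self.scale_hint not in ("linear", "log2"):
            raise UsageError(f"unknown scale_hint {self.scale_hint!r}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate feature ids: {dupes[:5]}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dupes[:5]}")
        arr = self.values.to_numpy()
        if arr.size and np.isinf(arr).any():
            raise FormatError("expression values must be finite or NA")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class GroupLabels:
    """sample id -> {normal, tumor} assignment for a two-group comparison."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        bad = {g for g in self.mapping.values() if g not in (NORMAL, TUMOR)}
        if bad:
            raise FormatError(f"labels must be '{NORMAL}' or '{TUMOR}', got {sorted(bad)}")

    def samples(self, group: str) -> list[str]:
        return [s for s, g in self.mapping.items() if g == group]

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = set(self.mapping) - set(matrix.sample_ids)
        if missing:
            raise FormatError(f"labeled samples absent from matrix: {sorted(missing)[:5]}")
        if not self.samples(NORMAL) or not self.samples(TUMOR):
            raise UsageError("both groups must be non-empty")


class TargetRecord(tuple):
    """(mirna_id, gene_id, source) prediction record."""

    __slots__ = ()

    def __new__(cls, mirna_id: str, gene_id: str, source: str):
        if not (mirna_id and gene_id and source):
            raise FormatError("TargetRecord fields must be non-empty")
        return super().__new__(cls, (mirna_id, gene_id, source))

    @property
    def mirna_id(self) -> str:
        return self[0]

    @property
    def gene_id(self) -> str:
        return self[1]

    @property
    def source(self) -> str:
        return self[2]


def ppi_edge(gene_a: str, gene_b: str) -> tuple[str, str] | None:
    """Canonical undirected edge: lexicographically ordered pair, or None for a self-loop."""
    if not gene_a or not gene_b:
        raise FormatError("PPI edge endpoints must be non-empty")
    if gene_a == gene_b:
        return None
    return (gene_a, gene_b) if gene_a < gene_b else (gene_b, gene_a)


@dataclass(frozen=True)
class TermRecord:
    term_id: str
    name: str
    namespace: str | None = None
    parents: tuple[str, ...] = ()


@dataclass
class Ontology:
    """An acyclic is_a hierarchy of terms; roots are terms without parents."""

    terms: dict[str, TermRecord]

    def __post_init__(self) -> None:
        for t in self.terms.values():
            for p in t.parents:
                if p not in self.terms:
                    raise StructuralError(f"term {t.term_id} has unknown parent {p}")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise StructuralError(f"ontology contains a cycle: {cyc}")

    def graph(self) -> nx.DiGraph:
        """child -> parent is_a digraph."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t in self.terms.values():
            for p in t.parents:
                g.add_edge(t.term_id, p)
        return g

    @property
    def roots(self) -> list[str]:
        return sorted(t.term_id for t in self.terms.values() if not t.parents)


@dataclass
class AnnotationSet:
    """term id -> annotated gene set; the universe is the union of all genes."""

    mapping: dict[str, frozenset[str]]

    @property
    def universe(self) -> frozenset[str]:
        if not self.mapping:
            return frozenset()
        return frozenset().union(*self.mapping.values())

    def validate_against(self, ontology: Ontology, lenient: bool = False) -> list[str]:
        unknown = sorted(t for t in self.mapping if t not in ontology.terms)
        if unknown and not lenient:
            raise StructuralError(f"annotations reference unknown terms: {unknown[:5]}")
        return unknown


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _tsv_rows(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_group_labels(path: str | Path) -> GroupLabels:
    mapping: dict[str, str] = {}
    for lineno, fields in _tsv_rows(path):
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        sample, group = fields
        if sample == "sample_id":  # optional header
            continue
        if group not in (NORMAL, TUMOR):
            raise FormatError(f"{path}:{lineno}: label {group!r} not in {{normal, tumor}}")
        if sample in mapping:
            raise FormatError(f"{path}:{lineno}: duplicate sample id {sample!r}")
        mapping[sample] = group
    return GroupLabels(mapping)


def read_expression_matrix(
    path: str | Path,
    labels_path: str | Path,
    *,
    scale_hint: str = "linear",
    drop_unlabeled: bool = False,
) -> tuple[ExpressionMatrix, GroupLabels]:
    """Read a header-rowed TSV matrix plus a sample_id<TAB>group label file.

    Unlabeled samples are rejected unless ``drop_unlabeled`` is set, in which
    case they are removed from the matrix.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse TSV matrix: {exc}") from exc
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate feature ids")
    if df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate sample ids in header")
    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col]
        cleaned = raw.where(raw != MISSING_TOKEN)
        try:
            values[col] = cleaned.astype(float)
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric cell in column {col!r}: {exc}") from exc
    labels = read_group_labels(labels_path)
    unlabeled = [s for s in values.columns if s not in labels.mapping]
    if unlabeled:
        if not drop_unlabeled:
            raise FormatError(f"{path}: unlabeled samples {unlabeled[:5]}")
        values = values.drop(columns=unlabeled)
    matrix = ExpressionMatrix(values, scale_hint=scale_hint)
    labels.validate_against(matrix)
    return matrix, labels


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(df.columns) + "\n")
        for fid, row in df.iterrows():
            cells = [MISSING_TOKEN if math.isnan(v) else repr(float(v)) for v in row]
            fh.write(str(fid) + "\t" + "\t".join(cells) + "\n")


def write_group_labels(labels: GroupLabels, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sample in labels.mapping:
            fh.write(f"{sample}\t{labels.mapping[sample]}\n")


def read_target_db(path: str | Path, source_name: str) -> list[TargetRecord]:
    """Read a two-column (mirna_id, gene_id) TSV; duplicates collapse."""
    if not source_name:
        raise UsageError("source_name must be non-empty")
    seen: dict[tuple[str, str], None] = {}
    for lineno, fields in _tsv_rows(path):
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        mirna, gene = fields
        if not mirna or not gene:
            raise FormatError(f"{path}:{lineno}: empty field")
        seen.setdefault((mirna, gene))
    return [TargetRecord(m, g, source_name) for m, g in seen]


def write_target_db(records: Iterable[TargetRecord], path: str | Path) -> None:
    rows = sorted({(r.mirna_id, r.gene_id) for r in records})
    with open(path, "w", encoding="utf-8") as fh:
        for m, g in rows:
            fh.write(f"{m}\t{g}\n")


def read_ppi_edges(path: str | Path) -> set[tuple[str, str]]:
    """Read a PPI edge list: 2-column TSV, or SIF (node, relation, node)."""
    edges: set[tuple[str, str]] = set()
    for lineno, fields in _tsv_rows(path):
        if len(fields) == 1:
            fields = fields[0].split()
        if len(fields) == 2:
            a, b = fields
        elif len(fields) == 3:
            a, _, b = fields
        else:
            raise FormatError(f"{path}:{lineno}: expected 2 (TSV) or 3 (SIF) columns")
        if not a or not b:
            raise FormatError(f"{path}:{lineno}: empty node name")
        edge = ppi_edge(a, b)
        if edge is not None:
            edges.add(edge)
    return edges


def write_ppi_edges(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(edges):
            fh.write(f"{a}\t{b}\n")


def read_obo(path: str | Path) -> Ontology:
    """Parse an OBO file, honoring only id / name / namespace / is_a."""
    import obonet

    graph = obonet.read_obo(path)
    terms = {}
    for node, data in graph.nodes(data=True):
        parents = tuple(sorted(
            v for u, v, key in graph.out_edges(node, keys=True) if key == "is_a"
        ))
        terms[node] = TermRecord(
            term_id=node,
            name=data.get("name", node),
            namespace=data.get("namespace"),
            parents=parents,
        )
    return Ontology(terms)


def read_ontology_tsv(terms_path: str | Path, edges_path: str | Path) -> Ontology:
    """Two-file ontology: terms (id, name[, namespace]) and child->parent edges."""
    raw: dict[str, tuple[str, str | None]] = {}
    for lineno, fields in _tsv_rows(terms_path):
        if fields[0] == "term_id":
            continue
        if len(fields) not in (2, 3):
            raise FormatError(f"{terms_path}:{lineno}: expected 2-3 columns")
        term_id, name = fields[0], fields[1]
        namespace = fields[2] if len(fields) == 3 and fields[2] else None
        if term_id in raw:
            raise FormatError(f"{terms_path}:{lineno}: duplicate term {term_id}")
        raw[term_id] = (name, namespace)
    parents: dict[str, set[str]] = {t: set() for t in raw}
    for lineno, fields in _tsv_rows(edges_path):
        if fields[0] == "child":
            continue
        if len(fields) != 2:
            raise FormatError(f"{edges_path}:{lineno}: expected 2 columns")
        child, parent = fields
        if child not in raw or parent not in raw:
            raise StructuralError(f"{edges_path}:{lineno}: edge references unknown term")
        if child == parent:
            raise StructuralError(f"{edges_path}:{lineno}: self-edge {child} -> {parent}")
        parents[child].add(parent)
    terms = {
        t: TermRecord(t, name, ns, tuple(sorted(parents[t])))
        for t, (name, ns) in raw.items()
    }
    return Ontology(terms)


def read_gmt(path: str | Path) -> AnnotationSet:
    mapping: dict[str, frozenset[str]] = {}
    for lineno, fields in _tsv_rows(path):
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT rows need term, description, >=1 gene")
        term_id = fields[0]
        genes = frozenset(g for g in fields[2:] if g)
        if not genes:
            raise FormatError(f"{path}:{lineno}: no genes for term {term_id}")
        mapping[term_id] = mapping.get(term_id, frozenset()) | genes
    return AnnotationSet(mapping)


def write_gmt(annotations: AnnotationSet, path: str | Path, descriptions: Mapping[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(annotations.mapping):
            desc = descriptions.get(term, term)
            genes = "\t".join(sorted(annotations.mapping[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n")


def read_ontology_and_annotations(
    onto_path: str | Path,
    gmt_path: str | Path,
    *,
    edges_path: str | Path | None = None,
    lenient: bool = False,
) -> tuple[Ontology, AnnotationSet]:
    """Load an ontology (OBO, or terms TSV + ``edges_path``) and GMT annotations."""
    if edges_path is not None:
        ontology = read_ontology_tsv(onto_path, edges_path)
    else:
        ontology = read_obo(onto_path)
    annotations = read_gmt(gmt_path)
    annotations.validate_against(ontology, lenient=lenient)
    return ontology, annotations


# ---------------------------------------------------------------------------
# Stage-output writer
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = {
    "de_mirna": ["feature_id", "d", "s", "q", "fc", "direction"],
    "de_gene": ["feature_id", "d", "s", "q", "fc", "direction"],
    "pairs": ["mirna_id", "mirna_direction", "gene_id", "gene_direction", "support", "sources"],
    "networks": ["mirna_id", "total", "l0_count", "l1_count"],
    "enrichment": ["mirna_id", "term_id", "term_name", "level", "k", "K", "n", "N",
                   "p", "p_adj", "cancer_related", "member_genes"],
    "roc": ["feature_id", "auc", "se", "z", "p", "n_pos", "n_neg"],
}


def write_outputs(results: Mapping[str, object], out_dir: str | Path) -> list[str]:
    """Write stage results as deterministic TSVs plus one SIF per network.

    ``results`` maps table names (see keys of the column registry) to pandas
    DataFrames, and may carry ``pins``: a list of built networks. Rows are
    sorted on their leading columns so repeated runs are byte-identical.
    Returns the manifest of written paths.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    manifest: list[str] = []
    # an entirely empty call still materializes the full header-only layout;
    # otherwise only the supplied tables are (re)written
    names = list(_TABLE_COLUMNS) if not results else [
        n for n in _TABLE_COLUMNS if n in results
    ]
    for name in names:
        columns = _TABLE_COLUMNS[name]
        frame = results.get(name)
        if frame is None:
            frame = pd.DataFrame(columns=columns)
        frame = pd.DataFrame(frame)
        missing_cols = [c for c in columns if c not in frame.columns]
        if not frame.empty and missing_cols:
            raise UsageError(f"table {name!r} lacks columns {missing_cols}")
        if frame.empty:
            frame = pd.DataFrame(columns=columns)
        frame = frame[columns].sort_values(columns[:2], kind="mergesort")
        path = out_dir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
        manifest.append(str(path))
    pins = results.get("pins") or []
    if pins:
        net_dir = out_dir / "nets"
        net_dir.mkdir(exist_ok=True)
        for pin in pins:
            path = net_dir / f"{pin.mirna_id}.sif"
            with open(path, "w", encoding="utf-8") as fh:
                for gene in sorted(pin.l0):
                    fh.write(f"{pin.mirna_id}\ttargets\t{gene}\n")
                for a, b in sorted(pin.edges):
                    fh.write(f"{a}\tpp\t{b}\n")
            manifest.append(str(path))
    return manifest
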