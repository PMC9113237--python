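"""Readers and writers for the on-disk formats used throughout the package.

Formats
-------
expression matrix
    Tab-separated text, one header line of gene names, one row per
    experiment.  A ``transpose`` flag supports genes-in-rows files whose
    first column holds the gene name.
annotation sidecar
    Tab-separated: ``row_index<TAB>kind[<TAB>genes[<TAB>extra]]`` where
    *kind* is one of :data:`ANNOTATION_KINDS`, *genes* is a comma-separated
    list of gene names (knockout / knockdown), and *extra* carries the time
    point for time-series rows.
TF list
    Plain text, one gene name per line.
goldstandard
    Three-column TSV ``regulator<TAB>target<TAB>{0,1}`` where 1 declares a
    verified edge and 0 a declared negative; absent pairs are unknown.
predictions
    Three-column TSV ``regulator<TAB>target<TAB>score`` sorted by
    descending score.

Gene identity is by exact, case-sensitive string match.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DataIOError",
    "ExpressionParseError",
    "ExpressionFormatError",
    "ExpressionDomainError",
    "GeneReferenceError",
    "Annotation",
    "WILD_TYPE",
    "ExpressionDataset",
    "TFList",
    "GoldStandard",
    "EdgeRanking",
    "read_expression",
    "write_expression",
    "read_annotations",
    "write_annotations",
    "read_tf_list",
    "read_goldstandard",
    "write_goldstandard",
    "read_edge_ranking",
    "write_edge_ranking",
    "ranking_to_matrix",
    "concatenate",
]

#: significant digits used when serializing scores, chosen so that float64
#: values round-trip bit-exactly through text
_FLOAT_FMT = "%.17g"

ANNOTATION_KINDS = ("wild_type", "knockout", "knockdown", "time_series", "other")


class DataIOError(Exception):
    """Base class for all I/O and validation failures in this module."""


class ExpressionParseError(DataIOError):
    """A cell could not be parsed as a finite number."""


class ExpressionFormatError(DataIOError):
    """Structural problem: ragged rows, missing header, bad sidecar line."""


class ExpressionDomainError(DataIOError):
    """A value violates the non-negativity assumption on expression data."""


class GeneReferenceError(DataIOError):
    """A file references a gene name absent from the dataset."""


@dataclasses.dataclass(frozen=True)
class Annotation:
    """Per-experiment label describing how a row was produced."""

    kind: str = "wild_type"
    genes: frozenset = frozenset()
    series_id: str | None = None
    time: float | None = None

    def __post_init__(self):
        if self.kind not in ANNOTATION_KINDS:
            raise ExpressionFormatError(
                f"unknown annotation kind {self.kind!r}; expected one of {ANNOTATION_KINDS}"
            )
        object.__setattr__(self, "genes", frozenset(self.genes))

    @property
    def is_single_knockout(self) -> bool:
        return self.kind == "knockout" and len(self.genes) == 1


WILD_TYPE = Annotation("wild_type")


@dataclasses.dataclass
class ExpressionDataset:
    """An experiments x genes matrix of non-negative expression levels.

    Attributes
    ----------
    values:
        ``(n_experiments, n_genes)`` float array, all entries >= 0.
    gene_names:
        Unique identifiers, one per column.
    annotations:
        One :class:`Annotation` per row.
    """

    values: np.ndarray
    gene_names: list[str]
    annotations: list[Annotation] = dataclasses.field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ExpressionFormatError("expression values must be a 2-D matrix")
        self.gene_names = list(self.gene_names)
        if len(self.gene_names) != self.values.shape[1]:
            raise ExpressionFormatError(
                f"{len(self.gene_names)} gene names for {self.values.shape[1]} columns"
            )
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ExpressionFormatError("gene names are not unique")
        if not np.all(np.isfinite(self.values)):
            raise ExpressionParseError("expression matrix contains non-finite values")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ExpressionDomainError(
                f"negative expression value at row {i}, gene {self.gene_names[j]}: "
                "expression levels are assumed non-negative"
            )
        if not self.annotations:
            self.annotations = [WILD_TYPE] * self.values.shape[0]
        if len(self.annotations) != self.values.shape[0]:
            raise ExpressionFormatError(
                f"{len(self.annotations)} annotations for {self.values.shape[0]} rows"
            )
        m = self.values.shape[1]
        for r, ann in enumerate(self.annotations):
            if any(g < 0 or g >= m for g in ann.genes):
                raise GeneReferenceError(
                    f"annotation of row {r} references a gene index outside 0..{m - 1}"
                )

    @property
    def n_experiments(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, name: str) -> int:
        try:
            return self.gene_names.index(name)
        except ValueError:
            raise GeneReferenceError(f"unknown gene name {name!r}") from None

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionDataset):
            return NotImplemented
        return (
            self.gene_names == other.gene_names
            and self.annotations == other.annotations
            and self.values.shape == other.values.shape
            and bool(np.array_equal(self.values, other.values))
        )


@dataclasses.dataclass(frozen=True)
class TFList:
    """Set of gene indices eligible as regulators.

    ``members`` defaults to all genes when no explicit list is supplied.
    """

    members: frozenset
    n_genes: int

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(self.members))
        if any(g < 0 or g >= self.n_genes for g in self.members):
            raise GeneReferenceError("TF index outside 0..n_genes-1")

    @classmethod
    def all_genes(cls, n_genes: int) -> "TFList":
        return cls(frozenset(range(n_genes)), n_genes)

    def mask(self) -> np.ndarray:
        out = np.zeros(self.n_genes, dtype=bool)
        out[list(self.members)] = True
        return out

    def __contains__(self, idx: int) -> bool:
        return idx in self.members

    def __len__(self) -> int:
        return len(self.members)


@dataclasses.dataclass
class GoldStandard:
    """Directed graph of verified regulatory links, by gene index.

    ``declared_negatives`` holds pairs verified absent; pairs in neither set
    are unknown.
    """

    edges: set
    n_genes: int
    declared_negatives: set = dataclasses.field(default_factory=set)

    def __post_init__(self):
        self.edges = {(int(i), int(j)) for i, j in self.edges}
        self.declared_negatives = {(int(i), int(j)) for i, j in self.declared_negatives}
        for i, j in self.edges | self.declared_negatives:
            if i == j:
                raise ExpressionFormatError(f"self-loop ({i}, {i}) in goldstandard")
            if not (0 <= i < self.n_genes and 0 <= j < self.n_genes):
                raise GeneReferenceError(f"goldstandard pair ({i}, {j}) out of range")
        overlap = self.edges & self.declared_negatives
        if overlap:
            raise ExpressionFormatError(
                f"{len(overlap)} pairs are both edges and declared negatives"
            )

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclasses.dataclass
class EdgeRanking:
    """Ordered list of (regulator name, target name, score) predictions."""

    entries: list

    def __post_init__(self):
        self.entries = [(str(a), str(b), float(s)) for a, b, s in self.entries]
        seen = set()
        prev = np.inf
        for a, b, s in self.entries:
            if a == b:
                raise ExpressionFormatError(f"self-loop {a}->{b} in ranking")
            if (a, b) in seen:
                raise ExpressionFormatError(f"duplicate pair {a}->{b} in ranking")
            seen.add((a, b))
            if s > prev:
                raise ExpressionFormatError("ranking scores are not non-increasing")
            prev = s

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def pairs(self, gene_names: Sequence[str]) -> list:
        """Resolve entries to (regulator index, target index) pairs."""
        index = {g: k for k, g in enumerate(gene_names)}
        out = []
        for a, b, _ in self.entries:
            if a not in index or b not in index:
                raise GeneReferenceError(f"ranking references unknown gene {a!r} or {b!r}")
            out.append((index[a], index[b]))
        return out


# ---------------------------------------------------------------------------
# expression matrices


def _parse_cell(field: str, row: int, gene: str) -> float:
    try:
        value = float(field)
    except ValueError:
        raise ExpressionParseError(
            f"non-numeric value {field!r} at row {row}, column {gene}"
        ) from None
    if not np.isfinite(value):
        raise ExpressionParseError(f"non-finite value {field!r} at row {row}, column {gene}")
    if value < 0:
        raise ExpressionDomainError(
            f"negative value {value} at row {row}, column {gene}: "
            "expression levels are assumed non-negative"
        )
    return value


def read_expression(
    path, annotation_path=None, *, transpose: bool = False
) -> ExpressionDataset:
    """Read a tab-separated expression matrix.

    Parameters
    ----------
    path:
        TSV file with a header of gene names and one row per experiment.
    annotation_path:
        Optional sidecar mapping row indices to experiment annotations;
        rows without an entry default to wild-type.
    transpose:
        Set when the file stores genes in rows (first column = gene name).
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ExpressionFormatError(f"{path}: empty file")

    if transpose:
        gene_names: list[str] = []
        columns: list[list[float]] = []
        width = None
        for r, line in enumerate(lines[1:]):
            fields = line.split("\t")
            name, cells = fields[0], fields[1:]
            if width is None:
                width = len(cells)
            elif len(cells) != width:
                raise ExpressionFormatError(
                    f"{path}: row {r} has {len(cells)} values, expected {width}"
                )
            gene_names.append(name)
            columns.append([_parse_cell(c, k, name) for k, c in enumerate(cells)])
        values = np.array(columns, dtype=float).T if columns else np.empty((0, 0))
    else:
        gene_names = lines[0].split("\t")
        m = len(gene_names)
        rows = []
        for r, line in enumerate(lines[1:]):
            fields = line.split("\t")
            if len(fields) != m:
                raise ExpressionFormatError(
                    f"{path}: row {r} has {len(fields)} fields, expected {m}"
                )
            rows.append([_parse_cell(f, r, gene_names[c]) for c, f in enumerate(fields)])
        values = np.array(rows, dtype=float) if rows else np.empty((0, m))

    annotations = None
    if annotation_path is not None:
        annotations = read_annotations(annotation_path, gene_names, values.shape[0])
    return ExpressionDataset(values, gene_names, annotations or [])


def write_expression(dataset: ExpressionDataset, path, annotation_path=None) -> None:
    """Write a dataset as TSV (and its annotations when a path is given)."""
    with open(path, "w") as fh:
        fh.write("\t".join(dataset.gene_names) + "\n")
        for row in dataset.values:
            fh.write("\t".join(_FLOAT_FMT % v for v in row) + "\n")
    if annotation_path is not None:
        write_annotations(dataset, annotation_path)


def read_annotations(path, gene_names: Sequence[str], n_rows: int) -> list:
    """Parse an annotation sidecar into one :class:`Annotation` per row."""
    index = {g: k for k, g in enumerate(gene_names)}
    annotations = [WILD_TYPE] * n_rows
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ExpressionFormatError(
                    f"{path}:{lineno}: expected at least 2 tab-separated fields"
                )
            try:
                row = int(fields[0])
            except ValueError:
                raise ExpressionFormatError(
                    f"{path}:{lineno}: row index {fields[0]!r} is not an integer"
                ) from None
            if not 0 <= row < n_rows:
                raise ExpressionFormatError(
                    f"{path}:{lineno}: row index {row} outside 0..{n_rows - 1}"
                )
            kind = fields[1]
            genes: frozenset = frozenset()
            series_id = None
            time = None
            if kind in ("knockout", "knockdown"):
                if len(fields) < 3 or not fields[2]:
                    raise ExpressionFormatError(
                        f"{path}:{lineno}: {kind} annotation requires gene names"
                    )
                names = fields[2].split(",")
                missing = [g for g in names if g not in index]
                if missing:
                    raise GeneReferenceError(
                        f"{path}:{lineno}: unknown gene name(s) {missing}"
                    )
                genes = frozenset(index[g] for g in names)
            elif kind == "time_series":
                series_id = fields[2] if len(fields) > 2 and fields[2] else None
                time = float(fields[3]) if len(fields) > 3 and fields[3] else None
            annotations[row] = Annotation(kind, genes, series_id, time)
    return annotations


def write_annotations(dataset: ExpressionDataset, path) -> None:
    with open(path, "w") as fh:
        for r, ann in enumerate(dataset.annotations):
            if ann.kind == "wild_type":
                continue
            names = ",".join(sorted(dataset.gene_names[g] for g in ann.genes))
            if ann.kind == "time_series":
                fh.write(
                    f"{r}\t{ann.kind}\t{ann.series_id or ''}\t"
                    f"{'' if ann.time is None else _FLOAT_FMT % ann.time}\n"
                )
            else:
                fh.write(f"{r}\t{ann.kind}\t{names}\n")


# ---------------------------------------------------------------------------
# TF lists and goldstandards


def read_tf_list(path, gene_names: Sequence[str]) -> TFList:
    """Read a one-name-per-line TF list, resolved against ``gene_names``."""
    index = {g: k for k, g in enumerate(gene_names)}
    members = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            name = line.strip()
            if not name or name.startswith("#"):
                continue
            if name not in index:
                raise GeneReferenceError(f"{path}:{lineno}: unknown gene name {name!r}")
            members.add(index[name])
    return TFList(frozenset(members), len(gene_names))


def read_goldstandard(path, gene_names: Sequence[str]) -> GoldStandard:
    """Read a 3-column edge list; self-loop lines are dropped with a warning."""
    index = {g: k for k, g in enumerate(gene_names)}
    edges: set = set()
    negatives: set = set()
    n_self_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                raise ExpressionFormatError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated fields"
                )
            a, b = fields[0], fields[1]
            label = fields[2] if len(fields) == 3 else "1"
            if a not in index or b not in index:
                raise GeneReferenceError(
                    f"{path}:{lineno}: unknown gene name {a!r} or {b!r}"
                )
            if a == b:
                n_self_loops += 1
                continue
            if label not in ("0", "1"):
                raise ExpressionFormatError(
                    f"{path}:{lineno}: third column must be 0 or 1, got {label!r}"
                )
            pair = (index[a], index[b])
            (edges if label == "1" else negatives).add(pair)
    if n_self_loops:
        warnings.warn(
            f"{path}: rejected {n_self_loops} self-loop line(s)", stacklevel=2
        )
    return GoldStandard(edges, len(gene_names), negatives)


def write_goldstandard(gold: GoldStandard, gene_names: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        for i, j in sorted(gold.edges):
            fh.write(f"{gene_names[i]}\t{gene_names[j]}\t1\n")
        for i, j in sorted(gold.declared_negatives):
            fh.write(f"{gene_names[i]}\t{gene_names[j]}\t0\n")


# ---------------------------------------------------------------------------
# rankings


def write_edge_ranking(
    scores: np.ndarray, gene_names: Sequence[str], path, max_edges: int | None = None
) -> EdgeRanking:
    """Serialize a score matrix as a descending DREAM-style edge list.

    Zero-score pairs and the diagonal are omitted; ties are broken by
    (regulator index, target index) ascending.  Returns the ranking written.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ExpressionParseError("score matrix contains non-finite values")
    if max_edges is not None and max_edges < 1:
        raise ValueError("max_edges must be >= 1")
    m = scores.shape[0]
    ii, jj = np.nonzero(scores)
    keep = ii != jj
    ii, jj = ii[keep], jj[keep]
    order = np.lexsort((jj, ii, -scores[ii, jj]))
    if max_edges is not None:
        order = order[:max_edges]
    entries = [(gene_names[i], gene_names[j], scores[i, j]) for i, j in zip(ii[order], jj[order])]
    if not entries:
        warnings.warn("all scores are zero: writing an empty ranking", stacklevel=2)
    with open(path, "w") as fh:
        for a, b, s in entries:
            fh.write(f"{a}\t{b}\t{_FLOAT_FMT % s}\n")
    return EdgeRanking(entries)


def read_edge_ranking(path) -> EdgeRanking:
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ExpressionFormatError(
                    f"{path}:{lineno}: expected 3 tab-separated fields"
                )
            try:
                score = float(fields[2])
            except ValueError:
                raise ExpressionParseError(
                    f"{path}:{lineno}: non-numeric score {fields[2]!r}"
                ) from None
            entries.append((fields[0], fields[1], score))
    return EdgeRanking(entries)


def ranking_to_matrix(
    ranking: EdgeRanking, gene_names: Sequence[str], fill: float = 0.0
) -> np.ndarray:
    """Expand a ranking into a score matrix; unranked pairs get ``fill``."""
    m = len(gene_names)
    out = np.full((m, m), float(fill))
    np.fill_diagonal(out, 0.0)
    for (i, j), (_, _, s) in zip(ranking.pairs(gene_names), ranking):
        out[i, j] = s
    return out


# ---------------------------------------------------------------------------
# misc


def concatenate(datasets: Iterable[ExpressionDataset]) -> ExpressionDataset:
    """Stack datasets sharing the same gene panel into one matrix."""
    datasets = list(datasets)
    if not datasets:
        raise ValueError("no datasets to concatenate")
    names = datasets[0].gene_names
    for ds in datasets[1:]:
        if ds.gene_names != names:
            raise GeneReferenceError("cannot concatenate datasets with different gene panels")
    values = np.vstack([ds.values for ds in datasets])
    annotations = [a for ds in datasets for a in ds.annotations]
    return ExpressionDataset(values, names, annotations)
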