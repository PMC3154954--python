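"""Readers and writers for the pipeline's external artifacts.

Every downstream stage operates on the in-memory containers defined here:
an :class:`ExpressionBundle` (linear-scale intensities + detection p-values +
sample design), a :class:`GeneSetCollection` (GMT), an
:class:`InteractionNetwork` (SIF / two-column edge list) and an
:class:`AnnotationMap` (three-column gene/term/class table).  Parsing is
strict: malformed input raises :class:`ValidationError`, never silently
coerces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger("varcon")

DESIGN_COLUMNS = ("donor_id", "group_label", "cell_type", "replicate_id")


class ValidationError(ValueError):
    """Raised when an external artifact violates its format contract."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionBundle:
    """Expression matrix with matching detection p-values and sample design.

    Parameters
    ----------
    expression
        probe x sample matrix of non-negative intensities.  Linear scale by
        default; ``is_log2`` declares pre-logged input (CV is scale
        sensitive, so the bundle must know).
    detection
        probe x sample matrix of detection p-values in [0, 1], sharing the
        expression index.  May be ``None`` when the platform provides no
        detection scores; the detection filter is then unavailable.
    design
        one row per sample: donor_id, group_label, cell_type, replicate_id.
    """

    expression: pd.DataFrame
    detection: pd.DataFrame | None
    design: pd.DataFrame
    is_log2: bool = False

    def __post_init__(self) -> None:
        validate_bundle(self)

    @property
    def probes(self) -> pd.Index:
        return self.expression.index

    @property
    def samples(self) -> pd.Index:
        return self.expression.columns

    def groups(self) -> list[str]:
        return list(pd.unique(self.design["group_label"]))

    def samples_in_group(self, label: str) -> list[str]:
        d = self.design
        return list(d.index[d["group_label"] == label])

    def replicate_counts(self) -> pd.Series:
        """Number of samples per donor (replicate structure)."""
        return self.design.groupby("donor_id").size()


def validate_bundle(bundle: ExpressionBundle) -> None:
    expr, det, design = bundle.expression, bundle.detection, bundle.design
    if expr.index.has_duplicates:
        dup = expr.index[expr.index.duplicated()][0]
        raise ValidationError(f"duplicate probe id in expression matrix: {dup!r}")
    if det is not None:
        missing_s = expr.columns.difference(det.columns)
        if len(missing_s):
            raise ValidationError(
                f"detection matrix missing sample {missing_s[0]!r}"
            )
        missing_p = expr.index.difference(det.index)
        if len(missing_p):
            raise ValidationError(
                f"detection matrix missing probe {missing_p[0]!r}"
            )
        # reindex to the expression layout so downstream code can align blindly
        bundle.detection = det = det.reindex(index=expr.index, columns=expr.columns)
        vals = det.to_numpy()
        if ((vals < 0) | (vals > 1)).any():
            bad = det.columns[((vals < 0) | (vals > 1)).any(axis=0)][0]
            raise ValidationError(
                f"detection p-value outside [0, 1] in sample {bad!r}"
            )
    if not bundle.is_log2 and (expr.to_numpy() < 0).any():
        bad = expr.columns[(expr.to_numpy() < 0).any(axis=0)][0]
        raise ValidationError(f"negative intensity in sample {bad!r}")
    for col in DESIGN_COLUMNS:
        if col not in design.columns:
            raise ValidationError(f"design table missing column {col!r}")
    extra = expr.columns.difference(design.index)
    if len(extra):
        raise ValidationError(f"sample {extra[0]!r} absent from design table")
    if design.index.has_duplicates:
        dup = design.index[design.index.duplicated()][0]
        raise ValidationError(f"sample {dup!r} appears twice in design table")
    # keep design restricted and ordered to the expression columns
    bundle.design = design.loc[expr.columns]


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a probe universe (GMT semantics)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: list[str] = field(default_factory=list)
    original_sizes: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class InteractionNetwork:
    """Undirected simple interaction graph plus a probe -> node mapping.

    ``node_map`` may map several probes onto one node (many-to-one is legal
    and recorded explicitly rather than resolved at ingestion time).
    """

    graph: nx.Graph
    node_map: dict[str, str] = field(default_factory=dict)

    def degree_of(self, probe: str) -> int | None:
        node = self.node_map.get(probe, probe)
        if node in self.graph:
            return int(self.graph.degree[node])
        return None

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class AnnotationMap:
    """(gene, term, ontology_class) records, deduplicated within class."""

    records: pd.DataFrame  # columns: gene_id, term_id, ontology_class

    def classes(self) -> list[str]:
        return list(pd.unique(self.records["ontology_class"]))

    def by_class(self, ontology_class: str) -> pd.DataFrame:
        r = self.records
        return r[r["ontology_class"] == ontology_class]

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_matrix(path: str | Path) -> pd.DataFrame:
    """Rectangular TSV/CSV with header row of sample ids, first column probes."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_expression_bundle(
    expr_path: str | Path,
    detection_path: str | Path | None,
    design_path: str | Path,
    is_log2: bool = False,
) -> ExpressionBundle:
    """Read expression + detection + design files into a validated bundle.

    Probe and sample order follow the expression file; the detection matrix
    is reindexed to match.  ``detection_path=None`` disables the detection
    filter (a warning is logged).
    """
    expr = _read_matrix(expr_path)
    if detection_path is None:
        logger.warning("no detection matrix supplied; detection filter disabled")
        det = None
    else:
        det = _read_matrix(detection_path)
    design = _read_matrix(design_path)
    design.index.name = "sample_id"
    bundle = ExpressionBundle(expr, det, design, is_log2=is_log2)
    logger.info(
        "read bundle: %d probes x %d samples, %d donors",
        len(bundle.probes), len(bundle.samples), bundle.design["donor_id"].nunique(),
    )
    return bundle


def write_expression_bundle(bundle: ExpressionBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle back to TSV files; inverse of :func:`read_expression_bundle`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"expression": out / "expression.tsv", "design": out / "design.tsv"}
    bundle.expression.to_csv(paths["expression"], sep="\t")
    bundle.design.to_csv(paths["design"], sep="\t")
    if bundle.detection is not None:
        paths["detection"] = out / "detection.tsv"
        bundle.detection.to_csv(paths["detection"], sep="\t")
    return paths


def read_gene_sets(gmt_path: str | Path, universe: list[str]) -> GeneSetCollection:
    """Parse a GMT file and intersect every set with the probe universe.

    Sets that are empty after intersection are dropped with a warning;
    original and retained sizes are recorded.  Overlapping sets are legal.
    """
    path = Path(gmt_path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    uni = set(universe)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    original_sizes: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: GMT line needs >=3 fields")
            name, desc, members = parts[0], parts[1], parts[2:]
            if name in sets or name in original_sizes:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            original_sizes[name] = len(members)
            kept = [m for m in members if m in uni]
            if not kept:
                logger.warning("gene set %r empty after universe intersection; dropped", name)
                continue
            sets[name] = kept
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions, list(universe), original_sizes)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")
    return path


def read_network(edge_path: str | Path, node_map: dict[str, str] | None = None) -> InteractionNetwork:
    """Read a SIF ("A pp B") or two-column TSV edge list.

    Self-loops are removed and duplicate edges collapsed; the result is an
    undirected simple graph.  An empty file yields an empty network.
    """
    path = Path(edge_path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    graph = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            tokens = line.split("\t") if "\t" in line else line.split()
            if len(tokens) == 2:
                a, b = tokens
            elif len(tokens) == 3:  # SIF: source, interaction type, target
                a, _, b = tokens
            else:
                raise ValidationError(f"{path}:{lineno}: expected 2 or 3 tokens")
            if a == b:
                continue  # self-loop
            graph.add_edge(a, b)
    logger.info("read network: %d nodes, %d edges", graph.number_of_nodes(), graph.number_of_edges())
    return InteractionNetwork(graph, node_map or {})


def write_network(network: InteractionNetwork, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(network.graph.edges()):
            fh.write(f"{a}\t{b}\n")
    return path


def read_annotations(path: str | Path, strict_classes: tuple[str, ...] | None = None) -> AnnotationMap:
    """Read a three-column gene/term/class TSV into an :class:`AnnotationMap`.

    Duplicate (gene, term) pairs within a class are collapsed.  When
    ``strict_classes`` is given, any other class label is an error.
    """
    p = Path(path)
    if not p.exists():
        raise ValidationError(f"file not found: {p}")
    df = pd.read_csv(p, sep="\t", header=None, names=["gene_id", "term_id", "ontology_class"], dtype=str)
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax()) + 1
        raise ValidationError(f"{p}:{row}: annotation row needs 3 columns")
    if strict_classes is not None:
        unknown = set(df["ontology_class"]) - set(strict_classes)
        if unknown:
            raise ValidationError(f"unknown ontology class {sorted(unknown)[0]!r}")
    df = df.drop_duplicates().reset_index(drop=True)
    return AnnotationMap(df)


def write_annotations(annotations: AnnotationMap, path: str | Path) -> Path:
    path = Path(path)
    annotations.records.to_csv(path, sep="\t", header=False, index=False)
    return path
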