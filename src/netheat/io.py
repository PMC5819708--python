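"""Readers, writers and the shared data model.

All external formats are plain text: expression as a TSV matrix plus a CSV
sample-metadata table, interactomes as two-column edge lists, gene sets as
GMT, phenotypes as CSV, and the optional probe-to-gene map as a two-column
TSV.  Gene identifiers are official gene symbols throughout; mapping between
namespaces is the caller's responsibility via the probe map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("netheat")

GROUPS = ("COPD", "healthy")
TIMEPOINTS = ("pre", "post")


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass
class ExpressionMatrix:
    """Genes x samples log2-intensity matrix with per-sample metadata.

    ``values`` has one row per gene and one column per sample.  ``metadata``
    is indexed by sample id with columns ``group`` (COPD/healthy),
    ``timepoint`` (pre/post) and ``subject``.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("duplicate gene symbols")
        if len(set(self.samples)) != len(self.samples):
            raise FormatError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("non-finite expression values")
        missing = [s for s in self.samples if s not in self.metadata.index]
        if missing:
            raise FormatError(f"samples missing from metadata: {missing}")
        for col in ("group", "timepoint", "subject"):
            if col not in self.metadata.columns:
                raise FormatError(f"metadata lacks required column '{col}'")
        self.metadata = self.metadata.loc[self.samples]

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        idx = [self.samples.index(s) for s in samples]
        return ExpressionMatrix(
            genes=list(self.genes),
            samples=list(samples),
            values=self.values[:, idx],
            metadata=self.metadata.loc[samples],
        )

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.genes)}
        idx = [pos[g] for g in genes]
        return ExpressionMatrix(
            genes=list(genes),
            samples=list(self.samples),
            values=self.values[idx, :],
            metadata=self.metadata,
        )


@dataclass
class InteractionNetwork:
    """Undirected PPI graph; nodes are gene symbols, no self-loops."""

    name: str
    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class GeneSetCollection:
    """GMT-style term -> (name, genes) mapping."""

    sets: dict[str, tuple[str, list[str]]]

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for _, genes in self.sets.values():
            out.update(genes)
        return out

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class PhenotypeTable:
    """Numeric clinical/metabolomic variables keyed by subject (and timepoint).

    ``frame`` is indexed by sample-like keys (``subject`` or
    ``subject:timepoint``); missing values stay as NaN and are handled
    pairwise-complete at correlation time.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        non_numeric = [
            c for c in self.frame.columns
            if not pd.api.types.is_numeric_dtype(self.frame[c])
        ]
        if non_numeric:
            raise FormatError(f"non-numeric phenotype columns: {non_numeric}")

    @property
    def variables(self) -> list[str]:
        return list(self.frame.columns)


@dataclass
class Contrast:
    """A differential condition: two-class-unpaired or paired (post vs pre).

    For ``two-class-unpaired`` the selectors are lists of sample ids for
    class A and class B (A vs B log-ratios).  For ``paired`` they are the
    post and pre sample lists; matching is by subject id.
    """

    label: str
    design: str  # "two-class-unpaired" | "paired"
    class_a: list[str] = field(default_factory=list)
    class_b: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.design not in ("two-class-unpaired", "paired"):
            raise ValueError(f"unknown design {self.design!r}")


def standard_contrasts(expr: ExpressionMatrix) -> dict[str, Contrast]:
    """The three study contrasts: COPD-DE, COPD-TE and Healthy-TE.

    COPD-DE compares pre-training COPD vs pre-training healthy samples
    (unpaired); the two training-effect contrasts compare post vs pre within
    each group (paired by subject).
    """
    md = expr.metadata

    def sel(group: str, tp: str) -> list[str]:
        mask = (md["group"] == group) & (md["timepoint"] == tp)
        return list(md.index[mask])

    return {
        "COPD-DE": Contrast("COPD-DE", "two-class-unpaired",
                            sel("COPD", "pre"), sel("healthy", "pre")),
        "COPD-TE": Contrast("COPD-TE", "paired",
                            sel("COPD", "post"), sel("COPD", "pre")),
        "Healthy-TE": Contrast("Healthy-TE", "paired",
                               sel("healthy", "post"), sel("healthy", "pre")),
    }


# ---------------------------------------------------------------------------
# readers


def read_probe_map(path) -> dict[str, str]:
    """Two-column TSV: probe id -> gene symbol."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{i}: expected 2 fields, got {len(parts)}")
            out[parts[0]] = parts[1]
    return out


def collapse_probes(frame: pd.DataFrame, probe_map: dict[str, str]) -> pd.DataFrame:
    """Map probe rows to genes; keep the probe with the highest mean intensity.

    Probes absent from the map are dropped.  Ties on mean intensity break
    lexicographically by probe id, so collapsing is deterministic.
    """
    keep_probe: dict[str, str] = {}
    best_mean: dict[str, float] = {}
    means = frame.mean(axis=1)
    for probe in sorted(frame.index):
        gene = probe_map.get(probe)
        if gene is None:
            continue
        m = float(means[probe])
        if gene not in keep_probe or m > best_mean[gene]:
            keep_probe[gene] = probe
            best_mean[gene] = m
    genes = sorted(keep_probe)
    out = frame.loc[[keep_probe[g] for g in genes]].copy()
    out.index = genes
    return out


def read_expression(path, metadata_path, probe_map_path=None) -> ExpressionMatrix:
    """Read a TSV expression matrix and join its CSV sample metadata.

    First matrix column holds gene (or probe) ids, the header row the sample
    ids.  When ``probe_map_path`` is given, probe rows are collapsed to genes
    by the highest-mean-intensity rule.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression cell ({exc})") from exc
    md = pd.read_csv(metadata_path, index_col=0)
    md.index = md.index.astype(str)
    missing = [s for s in frame.columns if s not in md.index]
    if missing:
        raise FormatError(f"samples absent from metadata: {missing}")
    if probe_map_path is not None:
        frame = collapse_probes(frame, read_probe_map(probe_map_path))
    elif frame.index.has_duplicates:
        raise FormatError(f"{path}: duplicate gene ids and no probe map supplied")
    return ExpressionMatrix(
        genes=list(frame.index),
        samples=list(frame.columns),
        values=frame.to_numpy(),
        metadata=md,
    )


def write_expression(expr: ExpressionMatrix, path, metadata_path) -> None:
    expr.frame.to_csv(path, sep="\t", index_label="gene")
    expr.metadata.to_csv(metadata_path, index_label="sample")


def read_network(path, name: str) -> InteractionNetwork:
    """Read a whitespace-separated two-column edge list.

    Duplicate edges (either orientation) collapse to one undirected edge;
    self-loops are dropped with a logged count; '#' lines are comments.
    """
    g = nx.Graph()
    n_loops = 0
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{i}: expected 2 tokens, got {len(parts)}")
            a, b = parts
            if a == b:
                n_loops += 1
                continue
            g.add_edge(a, b)
    if n_loops:
        logger.info("%s: dropped %d self-loop(s)", name, n_loops)
    if g.number_of_nodes() == 0:
        warnings.warn(f"network {name!r} is empty", stacklevel=2)
    return InteractionNetwork(name=name, graph=g)


def write_network(net: InteractionNetwork, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{a}\t{b}\n")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: term id, description, then one gene per field."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{i}: GMT line needs >=3 fields")
            term, desc = parts[0], parts[1]
            if term in sets:
                raise FormatError(f"{path}:{i}: duplicate term id {term!r}")
            genes = list(dict.fromkeys(g for g in parts[2:] if g))
            if not genes:
                raise FormatError(f"{path}:{i}: empty gene set {term!r}")
            sets[term] = (desc, genes)
    return GeneSetCollection(sets=sets)


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term, (desc, genes) in coll.sets.items():
            fh.write("\t".join([term, desc, *genes]) + "\n")


def read_phenotypes(path) -> PhenotypeTable:
    frame = pd.read_csv(path, index_col=0)
    frame.index = frame.index.astype(str)
    return PhenotypeTable(frame=frame)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.frame.to_csv(path, index_label="sample")


# ---------------------------------------------------------------------------
# harmonization


def harmonize(
    expr: ExpressionMatrix, nets: list[InteractionNetwork]
) -> tuple[ExpressionMatrix, list[InteractionNetwork], dict]:
    """Restrict each network to genes measured in ``expr``.

    Module discovery can only score genes that carry expression data, so each
    interactome is reduced to the induced subgraph on measured genes.  The
    expression matrix itself is returned unchanged (heat is defined on each
    network's nodes).  The report counts nodes retained/dropped per network.
    """
    measured = set(expr.genes)
    out_nets: list[InteractionNetwork] = []
    report: dict = {}
    for net in nets:
        keep = [n for n in net.graph.nodes if n in measured]
        sub = nx.Graph(net.graph.subgraph(keep))
        dropped = net.graph.number_of_nodes() - len(keep)
        report[net.name] = {
            "nodes_retained": len(keep),
            "nodes_dropped": dropped,
            "edges_retained": sub.number_of_edges(),
        }
        if sub.number_of_nodes() == 0:
            warnings.warn(
                f"network {net.name!r} shares no genes with the expression matrix",
                stacklevel=2,
            )
        out_nets.append(InteractionNetwork(name=net.name, graph=sub))
    return expr, out_nets, report
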