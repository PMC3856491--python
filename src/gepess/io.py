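"""Readers and writers for the five tabular inputs and derived outputs.

Input conventions
-----------------
* PPI network: two-column delimited edge list (default tab); lines starting
  with ``#`` are comments. Self-interactions and duplicate edges (in either
  orientation) are dropped and counted.
* Essential-protein list: one protein ID per line.
* Expression / localization / orthology: TSV with a header row; the first
  column holds protein IDs.

ID matching everywhere is exact, case-sensitive string match: ORF names are
case-stable and silent case-folding hides data bugs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: The 16 subcellular compartments used as localization indicator features.
DEFAULT_COMPARTMENTS: tuple[str, ...] = (
    "vacuole",
    "vesicles",
    "lysosome",
    "membrane",
    "mitochondrion",
    "peroxisome",
    "secretory_pathway",
    "cell_wall",
    "cytoskeleton",
    "endoplasmic_reticulum",
    "golgi",
    "transmembrane",
    "cytoplasm",
    "nucleus",
    "endosome",
    "extracellular",
)


class ParseError(ValueError):
    """Malformed input file; the message names the offending location."""


@dataclass
class InteractionNetwork:
    """Undirected simple graph of protein IDs.

    Invariants: no self-loops, no repeated edges, every edge endpoint is a
    node. Backed by a :class:`networkx.Graph`.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    @classmethod
    def from_edges(cls, edges, nodes=()) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v in edges:
            if u != v:
                g.add_edge(u, v)
        return cls(g)


@dataclass
class EssentialityLabels:
    """Binary essentiality labels over a protein universe.

    ``essential`` is always a subset of ``universe``; every protein in the
    universe is either essential or nonessential, never both or neither.
    """

    essential: set[str]
    universe: set[str]

    def __post_init__(self) -> None:
        if not self.essential <= self.universe:
            raise ValueError("essential proteins must be a subset of the universe")

    @property
    def nonessential(self) -> set[str]:
        return self.universe - self.essential

    @property
    def ratio(self) -> float:
        """Nonessential-to-essential ratio (e.g. 3926/1167 ~ 3.36)."""
        if not self.essential:
            raise ValueError("no essential proteins")
        return len(self.nonessential) / len(self.essential)

    def to_series(self) -> pd.Series:
        """0/1 label vector indexed by sorted protein ID."""
        ids = sorted(self.universe)
        return pd.Series([1 if p in self.essential else 0 for p in ids],
                         index=ids, dtype=int, name="essential")


def read_network(path, delimiter: str = "\t") -> InteractionNetwork:
    """Read a two-column edge list into an :class:`InteractionNetwork`.

    Self-loops and duplicate edges (in either orientation) are dropped with
    a logged count. A line with a column count other than two raises
    :class:`ParseError` naming the line number.
    """
    g = nx.Graph()
    n_self, n_dup, n_lines = 0, 0, 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter) if delimiter else line.split()
            if len(parts) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(parts)}"
                )
            u, v = parts[0].strip(), parts[1].strip()
            n_lines += 1
            if u == v:
                n_self += 1
                g.add_node(u)
                continue
            if g.has_edge(u, v):
                n_dup += 1
                continue
            g.add_edge(u, v)
    if n_lines == 0:
        logger.warning("read_network: %s contains no interactions", path)
    if n_self or n_dup:
        logger.info(
            "read_network: dropped %d self-interactions and %d repeated interactions",
            n_self, n_dup,
        )
    logger.info(
        "read_network: %d proteins, %d edges from %s",
        g.number_of_nodes(), g.number_of_edges(), path,
    )
    return InteractionNetwork(g)


def write_network(network: InteractionNetwork, path, delimiter: str = "\t") -> None:
    """Write the canonical edge list (sorted, one edge per line)."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in network.graph.edges):
            fh.write(f"{u}{delimiter}{v}\n")


def read_labels(path, network: InteractionNetwork) -> EssentialityLabels:
    """Read a one-ID-per-line essential list, restricted to network nodes.

    IDs absent from the network are counted and logged, never fatal.
    """
    listed: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            pid = raw.strip()
            if pid and not pid.startswith("#"):
                listed.add(pid)
    nodes = network.nodes
    essential = listed & nodes
    absent = len(listed - nodes)
    if absent:
        logger.info("read_labels: %d listed proteins absent from the network", absent)
    logger.info(
        "read_labels: %d of %d network proteins are essential",
        len(essential), len(nodes),
    )
    return EssentialityLabels(essential=essential, universe=nodes)


def write_labels(labels: EssentialityLabels, path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(labels.essential):
            fh.write(pid + "\n")


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    df.index.name = "protein"
    return df


def read_expression(path) -> pd.DataFrame:
    """Read a protein x sample expression matrix (TSV, header row).

    Coverage may be partial: proteins missing from the matrix simply have
    no row. A non-numeric cell raises :class:`ParseError` naming the
    protein and sample.
    """
    df = _read_table(path)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        r = bad.any(axis=1).idxmax()
        c = bad.loc[r].idxmax()
        raise ParseError(f"{path}: non-numeric expression value at protein {r!r}, sample {c!r}")
    if numeric.isna().any().any():
        raise ParseError(f"{path}: missing expression values")
    return numeric.astype(float)


def read_localization(path, compartments=DEFAULT_COMPARTMENTS,
                      strict: bool = True) -> pd.DataFrame:
    """Read a protein x compartment 0/1 membership table.

    Missing compartment columns are added as all-zero; extra columns raise.
    With ``strict`` (default) any value outside {0, 1} is an error;
    otherwise values are clamped into {0, 1}.
    """
    df = _read_table(path)
    extra = set(df.columns) - set(compartments)
    if extra:
        raise ParseError(f"{path}: unknown compartment columns {sorted(extra)}")
    df = df.apply(pd.to_numeric, errors="coerce")
    if df.isna().any().any():
        raise ParseError(f"{path}: non-numeric localization value")
    if strict and not df.isin([0, 1]).all().all():
        raise ParseError(f"{path}: localization values must be 0 or 1 (strict mode)")
    df = (df > 0).astype(int)
    for comp in compartments:
        if comp not in df.columns:
            df[comp] = 0
    return df[list(compartments)]


def read_orthology(path) -> pd.Series:
    """Read a per-protein conservation score table (TSV: protein, score).

    Scores must be nonnegative reals (e.g. number of reference organisms
    with an ortholog). Proteins absent from the table default to 0 at
    feature-assembly time.
    """
    df = _read_table(path)
    if df.shape[1] != 1:
        raise ParseError(f"{path}: expected exactly one score column, got {df.shape[1]}")
    scores = pd.to_numeric(df.iloc[:, 0], errors="coerce")
    if scores.isna().any():
        raise ParseError(f"{path}: non-numeric orthology score")
    if (scores < 0).any():
        raise ParseError(f"{path}: orthology scores must be nonnegative")
    return scores.astype(float).rename("orthology")


def write_feature_table(features: pd.DataFrame, path) -> None:
    """Write the canonical feature table: protein ID column + one column
    per named feature, tab-separated."""
    features.to_csv(path, sep="\t", index_label="protein")


def read_feature_table(path) -> pd.DataFrame:
    return _read_table(path).astype(float)


def write_ranking(scores: pd.Series, path) -> None:
    """Write a prediction ranking (protein, score, rank), best first.

    Ties are broken by protein ID so the output is deterministic.
    """
    order = sorted(scores.index, key=lambda p: (-scores[p], p))
    with open(path, "w") as fh:
        fh.write("protein\tscore\trank\n")
        for rank, pid in enumerate(order, start=1):
            fh.write(f"{pid}\t{scores[pid]:.10g}\t{rank}\n")
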