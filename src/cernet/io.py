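"""Readers and writers for the tabular and graph formats the pipeline touches.

All tabular formats are TSV with UTF-8 encoding. Gene identifiers are opaque,
case-sensitive strings; no symbol or alias resolution is attempted. Missing
clinical cells are encoded as ``NA``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

RNA_CLASSES = ("lncRNA", "miRNA", "mRNA")
UNITS = ("counts", "FPKM", "RPM")
#: unordered interaction categories; files may use "-" or the en dash
PAIR_CLASSES = ("lncRNA-miRNA", "miRNA-mRNA", "lncRNA-mRNA")

#: which pair class joins two RNA classes
_CLASS_PAIR = {
    frozenset({"lncRNA", "miRNA"}): "lncRNA-miRNA",
    frozenset({"miRNA", "mRNA"}): "miRNA-mRNA",
    frozenset({"lncRNA", "mRNA"}): "lncRNA-mRNA",
}


class FormatError(ValueError):
    """A file violated the format contract; the message locates the offence."""


def pair_class_for(class_a: str, class_b: str) -> str:
    """Return the interaction category joining two distinct RNA classes."""
    key = frozenset({class_a, class_b})
    if key not in _CLASS_PAIR:
        raise ValueError(f"no interaction category joins {class_a!r} and {class_b!r}")
    return _CLASS_PAIR[key]


@dataclass
class ExpressionTable:
    """A genes x samples abundance matrix for one RNA class.

    ``data`` holds non-negative, finite abundances (FPKM for lncRNA/mRNA,
    RPM for miRNA) with gene identifiers as the index and sample identifiers
    as the columns.
    """

    data: pd.DataFrame
    rna_class: str
    unit: str

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"unknown RNA class {self.rna_class!r}")
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        dup = self.data.index[self.data.index.duplicated()]
        if len(dup):
            raise FormatError(f"duplicate gene id {dup[0]!r}")
        dup = self.data.columns[self.data.columns.duplicated()]
        if len(dup):
            raise FormatError(f"duplicate sample id {dup[0]!r}")
        values = self.data.to_numpy()
        if values.size:
            if not np.isfinite(values).all():
                g, s = np.argwhere(~np.isfinite(values))[0]
                raise FormatError(
                    f"non-finite value at gene {self.data.index[g]!r}, "
                    f"sample {self.data.columns[s]!r}"
                )
            if (values < 0).any():
                g, s = np.argwhere(values < 0)[0]
                raise FormatError(
                    f"negative abundance at gene {self.data.index[g]!r}, "
                    f"sample {self.data.columns[s]!r}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def restrict_genes(self, genes: Iterable[str]) -> "ExpressionTable":
        keep = [g for g in genes if g in self.data.index]
        return ExpressionTable(self.data.loc[keep], self.rna_class, self.unit)


@dataclass
class SampleGroups:
    """Mapping of sample id to group label (``case`` or ``control``)."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        bad = {g for g in self.mapping.values() if g not in ("case", "control")}
        if bad:
            raise FormatError(f"unknown group label(s) {sorted(bad)}")
        if not self.case_ids or not self.control_ids:
            raise FormatError("both case and control groups must be non-empty")

    @property
    def case_ids(self) -> list[str]:
        return [s for s, g in self.mapping.items() if g == "case"]

    @property
    def control_ids(self) -> list[str]:
        return [s for s, g in self.mapping.items() if g == "control"]

    def labels_for(self, sample_ids: Iterable[str]) -> list[str]:
        missing = [s for s in sample_ids if s not in self.mapping]
        if missing:
            raise FormatError(f"sample {missing[0]!r} has no group assignment")
        return [self.mapping[s] for s in sample_ids]


@dataclass
class InteractionTable:
    """Orientation-free, deduplicated set of candidate gene-gene pairs."""

    pairs: set[tuple[frozenset, str]] = field(default_factory=set)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str]]
    ) -> "InteractionTable":
        pairs: set[tuple[frozenset, str]] = set()
        for a, b, pair_class in records:
            pair_class = pair_class.replace("–", "-")
            if a == b:
                raise FormatError(f"self-pair {a!r}")
            if pair_class not in PAIR_CLASSES:
                raise FormatError(f"unknown pair class {pair_class!r}")
            pairs.add((frozenset({a, b}), pair_class))
        return cls(pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        key = frozenset(pair)
        return any(k == key for k, _ in self.pairs)

    def has(self, a: str, b: str, pair_class: str) -> bool:
        return (frozenset({a, b}), pair_class) in self.pairs

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, pair_class in sorted(
            self.pairs, key=lambda kp: (sorted(kp[0]), kp[1])
        ):
            a, b = sorted(key)
            rows.append({"gene_a": a, "gene_b": b, "pair_class": pair_class})
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "pair_class"])


@dataclass
class ClinicalTable:
    """Samples x clinical parameters; missing values allowed (NaN)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        dup = self.data.index[self.data.index.duplicated()]
        if len(dup):
            raise FormatError(f"duplicate sample id {dup[0]!r}")
        dup = self.data.columns[self.data.columns.duplicated()]
        if len(dup):
            raise FormatError(f"duplicate parameter name {dup[0]!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def parameters(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets with optional descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_expression_table(path, rna_class: str, unit: str) -> ExpressionTable:
    """Read a TSV expression matrix (first column gene id, header sample ids)."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    raw.index = raw.index.astype(str)
    dup = raw.index[raw.index.duplicated()]
    if len(dup):
        raise FormatError(f"{path.name}: duplicate gene id {dup[0]!r}")
    dup = raw.columns[raw.columns.duplicated()]
    if len(dup):
        raise FormatError(f"{path.name}: duplicate sample id {dup[0]!r}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path.name}: non-numeric value {raw.iat[g, s]!r} at gene "
            f"{raw.index[g]!r}, sample {raw.columns[s]!r}"
        )
    if numeric.isna().to_numpy().any():
        g, s = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"{path.name}: missing value at gene {raw.index[g]!r}, "
            f"sample {raw.columns[s]!r}"
        )
    if (numeric.to_numpy() < 0).any():
        g, s = np.argwhere(numeric.to_numpy() < 0)[0]
        raise FormatError(
            f"{path.name}: negative value at gene {raw.index[g]!r}, "
            f"sample {raw.columns[s]!r}"
        )
    return ExpressionTable(numeric.astype(float), rna_class, unit)


def write_expression_table(table: ExpressionTable, path) -> None:
    # %.17g preserves float64 exactly, so read(write(t)) is the identity
    table.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_sample_groups(path) -> SampleGroups:
    """Read a two-column TSV of sample id and group label (case/control)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{Path(path).name}: expected columns sample_id, group")
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    if len(mapping) != len(df):
        raise FormatError(f"{Path(path).name}: duplicate sample id in group file")
    return SampleGroups(mapping)


def write_sample_groups(groups: SampleGroups, path) -> None:
    pd.DataFrame(
        {"sample_id": list(groups.mapping), "group": list(groups.mapping.values())}
    ).to_csv(path, sep="\t", index=False)


def read_interaction_table(path) -> InteractionTable:
    """Read a >=3-column TSV of candidate pairs (geneA, geneB, pair class)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 3:
        raise FormatError(
            f"{Path(path).name}: expected >= 3 columns (gene_a, gene_b, pair_class)"
        )
    return InteractionTable.from_records(
        df.iloc[:, :3].itertuples(index=False, name=None)
    )


def write_interaction_table(table: InteractionTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_clinical_table(path) -> ClinicalTable:
    """Read a samples x parameters TSV; ``NA`` marks a missing measurement."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], comment="#")
    df.index = df.index.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        s, p = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{Path(path).name}: non-numeric value {df.iat[s, p]!r} at sample "
            f"{df.index[s]!r}, parameter {df.columns[p]!r}"
        )
    return ClinicalTable(numeric.astype(float))


def write_clinical_table(table: ClinicalTable, path) -> None:
    table.data.to_csv(
        path, sep="\t", index_label="sample_id", na_rep="NA", float_format="%.17g"
    )


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: set name TAB description TAB member TAB member ..."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{Path(path).name}:{lineno}: expected >= 3 tab-separated fields"
                )
            name, description, *members = fields
            if name in sets:
                raise FormatError(f"{Path(path).name}:{lineno}: duplicate set {name!r}")
            members = [m for m in members if m]
            sets[name] = set(members)
            descriptions[name] = description
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def write_network(graph: nx.Graph, path, dialect: str = "sif") -> None:
    """Export a network as SIF or GraphML.

    SIF lines are ``nodeA TAB pair_class TAB nodeB``; an isolated node is
    emitted as a bare single-token line. An empty network yields a valid
    (empty) file.
    """
    dialect = dialect.lower()
    if dialect == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for a, b, attrs in sorted(graph.edges(data=True)):
                fh.write(f"{a}\t{attrs.get('pair_class', 'interacts')}\t{b}\n")
            for node in sorted(graph.nodes):
                if graph.degree(node) == 0:
                    fh.write(f"{node}\n")
    elif dialect == "graphml":
        out = nx.Graph()
        for node, attrs in graph.nodes(data=True):
            out.add_node(node, **{k: v for k, v in attrs.items() if v is not None})
        for a, b, attrs in graph.edges(data=True):
            clean = {
                k: v
                for k, v in attrs.items()
                if v is not None and not (isinstance(v, float) and math.isnan(v))
            }
            out.add_edge(a, b, **clean)
        nx.write_graphml(out, path)
    else:
        raise ValueError(f"unknown network dialect {dialect!r}")


def read_network(path, dialect: str = "sif") -> nx.Graph:
    dialect = dialect.lower()
    if dialect == "sif":
        graph = nx.Graph()
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) == 1:
                    graph.add_node(fields[0])
                elif len(fields) == 3:
                    a, pair_class, b = fields
                    graph.add_edge(a, b, pair_class=pair_class)
                else:
                    raise FormatError(
                        f"{Path(path).name}:{lineno}: SIF lines have 1 or 3 fields"
                    )
        return graph
    if dialect == "graphml":
        return nx.read_graphml(path)
    raise ValueError(f"unknown network dialect {dialect!r}")
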