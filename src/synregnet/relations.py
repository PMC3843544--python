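"""Typed regulator->target relation tables.

The regulatory system is defined by four directed relation classes between
three node classes (miRNA, TF, gene):

    mir2gene : miRNA represses a target gene
    mir2tf   : miRNA represses a transcription factor
    tf2gene  : TF transcriptionally regulates a gene
    tf2mir   : TF transcriptionally regulates a miRNA gene

All four are stored together in a single tab-delimited table with columns
``source_id``, ``target_id``, ``relation_class``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

RELATION_CLASSES = ("mir2gene", "mir2tf", "tf2gene", "tf2mir")

#: node class of (source, target) for each relation class
RELATION_ENDPOINTS = {
    "mir2gene": ("mirna", "gene"),
    "mir2tf": ("mirna", "tf"),
    "tf2gene": ("tf", "gene"),
    "tf2mir": ("tf", "mirna"),
}

COLUMNS = ("source_id", "target_id", "relation_class")


class RelationTableError(ValueError):
    """Malformed relation table (bad columns or unknown relation class)."""


@dataclass
class RelationTables:
    """The four typed edge lists, held as one tidy DataFrame."""

    edges: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=list(COLUMNS))
    )

    def __post_init__(self) -> None:
        missing = set(COLUMNS) - set(self.edges.columns)
        if missing:
            raise RelationTableError(f"missing columns: {sorted(missing)}")
        bad = set(self.edges["relation_class"]) - set(RELATION_CLASSES)
        if bad:
            raise RelationTableError(f"unknown relation classes: {sorted(bad)}")
        self.edges = self.edges.loc[:, list(COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.edges)

    def of_class(self, relation_class: str) -> pd.DataFrame:
        if relation_class not in RELATION_CLASSES:
            raise RelationTableError(f"unknown relation class: {relation_class}")
        return self.edges[self.edges["relation_class"] == relation_class]

    def edge_pairs(self, relation_class: str) -> list[tuple[str, str]]:
        sub = self.of_class(relation_class)
        return list(zip(sub["source_id"], sub["target_id"]))

    def class_counts(self) -> dict[str, int]:
        counts = self.edges["relation_class"].value_counts()
        return {rel: int(counts.get(rel, 0)) for rel in RELATION_CLASSES}

    def drop_duplicates(self) -> "RelationTables":
        return RelationTables(self.edges.drop_duplicates().reset_index(drop=True))

    def sorted(self) -> "RelationTables":
        frame = self.edges.sort_values(list(COLUMNS), kind="mergesort")
        return RelationTables(frame.reset_index(drop=True))

    def to_tsv(self, path: str | Path) -> None:
        # canonical sort so identical tables are byte-identical on disk
        self.sorted().edges.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RelationTables":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        return cls(frame)

    @classmethod
    def from_pairs(cls, pairs_by_class: dict[str, list[tuple[str, str]]]) -> "RelationTables":
        rows = []
        for rel, pairs in pairs_by_class.items():
            if rel not in RELATION_CLASSES:
                raise RelationTableError(f"unknown relation class: {rel}")
            rows.extend((s, t, rel) for s, t in pairs)
        return cls(pd.DataFrame(rows, columns=list(COLUMNS)))


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-id-per-line list, ignoring blanks and ``#`` comments."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))
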