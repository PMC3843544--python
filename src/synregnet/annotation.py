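"""Term -> gene annotation (GO-BP / pathway style), stored as GMT."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class TermAnnotation:
    """A mapping from functional term id to its member gene set.

    The GMT format is one term per line: term id, description, then the
    member gene ids, all tab-separated.
    """

    terms: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def genes(self, term: str) -> frozenset[str]:
        return self.terms[term]

    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.terms.values():
            out |= genes
        return frozenset(out)

    def add(self, term: str, genes, description: str = "") -> None:
        self.terms[term] = frozenset(genes)
        self.descriptions[term] = description

    def to_gmt(self, path: str | Path) -> None:
        lines = []
        for term in sorted(self.terms):
            desc = self.descriptions.get(term, "")
            members = "\t".join(sorted(self.terms[term]))
            lines.append(f"{term}\t{desc}\t{members}" if members else f"{term}\t{desc}")
        Path(path).write_text("".join(line + "\n" for line in lines))

    @classmethod
    def from_gmt(cls, path: str | Path) -> "TermAnnotation":
        ann = cls()
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            term, desc, members = parts[0], parts[1] if len(parts) > 1 else "", parts[2:]
            ann.add(term, [m for m in members if m], desc)
        return ann
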