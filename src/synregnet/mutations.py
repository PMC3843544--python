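"""Per-sample binary somatic mutation profiles."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd


@dataclass
class MutationProfile:
    """Binary gene x sample mutation calls (1 = mutated in that sample)."""

    calls: pd.DataFrame  # index: gene ids, columns: sample ids, values 0/1

    def __post_init__(self) -> None:
        values = self.calls.to_numpy()
        if values.size and not ((values == 0) | (values == 1)).all():
            raise ValueError("mutation calls must be binary")

    @property
    def genes(self) -> list[str]:
        return list(self.calls.index)

    def mutation_rates(self) -> pd.Series:
        """Per-gene fraction of samples carrying a mutation."""
        return self.calls.mean(axis=1)

    def mutated_genes(self, rate_threshold: float = 0.05) -> frozenset[str]:
        """Genes mutated in strictly more than ``rate_threshold`` of samples."""
        rates = self.mutation_rates()
        return frozenset(rates.index[rates > rate_threshold])

    def to_tsv(self, path: str | Path) -> None:
        self.calls.sort_index().to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MutationProfile":
        frame = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(frame)
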