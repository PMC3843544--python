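"""Expression preprocessing and disease-gene selection.

Input matrices are log2-scale intensities (microarray convention), genes or
probes in rows and samples in columns, with a case/control label per sample.
The selection pipeline is: filter rows with too many missing values, impute
the rest by K-nearest-row means, collapse probes of the same gene, call
differential expression by Welch's t-test with Benjamini-Hochberg FDR and a
linear fold-change threshold, and intersect with a curated disease list.
Bootstrap resampling of samples within groups measures the stability of the
selected set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.impute import KNNImputer

from .enrich import bh_adjust

logger = logging.getLogger(__name__)

GROUP_LABELS = ("case", "control")


class EmptyExpressionError(ValueError):
    """Raised when filtering removes every row of an expression matrix."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values with per-sample group labels.

    ``values``: rows are probe or gene ids, columns are sample ids.
    ``groups``: one label per column, ``case`` or ``control``.
    ``probe_gene_map``: optional probe id -> gene id; rows without an entry
    keep their own id as the gene id.
    """

    values: pd.DataFrame
    groups: Sequence[str]
    probe_gene_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.groups = list(self.groups)
        if len(self.groups) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.groups)} group labels for {self.values.shape[1]} samples"
            )
        bad = set(self.groups) - set(GROUP_LABELS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def n_case(self) -> int:
        return self.groups.count("case")

    @property
    def n_control(self) -> int:
        return self.groups.count("control")

    def group_columns(self, label: str) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.groups) if g == label])

    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix with a one-line group-label header (NA = missing)."""
        with open(path, "w") as handle:
            handle.write("gene_id\t" + "\t".join(map(str, self.values.columns)) + "\n")
            handle.write("!group\t" + "\t".join(self.groups) + "\n")
            self.values.to_csv(handle, sep="\t", header=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        with open(path) as handle:
            header = handle.readline().rstrip("\n").split("\t")
            group_line = handle.readline().rstrip("\n").split("\t")
            frame = pd.read_csv(
                handle, sep="\t", header=None, index_col=0, na_values=["NA"]
            )
        frame.columns = header[1:]
        frame.index.name = "gene_id"
        if group_line[0] != "!group":
            raise ValueError("expected a '!group' label line after the header")
        return cls(frame, group_line[1:])


def preprocess(
    matrix: ExpressionMatrix,
    max_missing_fraction: float = 0.05,
    k_neighbors: int = 10,
) -> ExpressionMatrix:
    """Filter, impute, and collapse an expression matrix.

    Rows whose missing fraction exceeds ``max_missing_fraction`` are dropped;
    the remaining missing cells are imputed as the mean of the ``k_neighbors``
    nearest rows under (nan-)Euclidean distance over co-observed columns;
    probes mapping to the same gene are averaged. The output has no missing
    entries.
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    values = matrix.values
    missing_frac = values.isna().mean(axis=1)
    kept = values.loc[missing_frac <= max_missing_fraction]
    if kept.empty:
        raise EmptyExpressionError(
            "all rows exceeded the missing-value threshold "
            f"({max_missing_fraction:.0%})"
        )
    if kept.isna().to_numpy().any():
        imputer = KNNImputer(n_neighbors=min(k_neighbors, len(kept) - 1) or 1)
        imputed = pd.DataFrame(
            imputer.fit_transform(kept.to_numpy()),
            index=kept.index,
            columns=kept.columns,
        )
    else:
        imputed = kept.astype(float)
    if matrix.probe_gene_map:
        gene_ids = [matrix.probe_gene_map.get(p, p) for p in imputed.index]
        imputed = imputed.groupby(pd.Index(gene_ids, name="gene_id")).mean()
    return ExpressionMatrix(imputed, matrix.groups, probe_gene_map=None)


def _de_table(
    values: np.ndarray,
    genes: Iterable[str],
    case_idx: np.ndarray,
    control_idx: np.ndarray,
    fc_threshold: float,
    fdr_threshold: float,
    log_base: float = 2.0,
) -> pd.DataFrame:
    case = values[:, case_idx]
    control = values[:, control_idx]
    mean_diff = case.mean(axis=1) - control.mean(axis=1)
    fold_change = np.power(log_base, mean_diff)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, pvals = stats.ttest_ind(case, control, axis=1, equal_var=False)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    qvals = bh_adjust(pvals)
    selected = (
        ((fold_change > fc_threshold) | (fold_change < 1.0 / fc_threshold))
        & (qvals < fdr_threshold)
    )
    return pd.DataFrame(
        {
            "gene": list(genes),
            "fold_change": fold_change,
            "p_value": pvals,
            "q_value": qvals,
            "selected": selected,
        }
    )


def differential_genes(
    matrix: ExpressionMatrix,
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-gene fold change, Welch p, BH q, and two-sided selection flag.

    Fold change is the linear-scale case/control ratio ``2**(mean difference)``
    of the log2 values; selection requires FC > ``fc_threshold`` or
    FC < 1/``fc_threshold`` together with q < ``fdr_threshold``.
    """
    if matrix.n_case < 2 or matrix.n_control < 2:
        raise ValueError("each group needs at least 2 samples")
    if matrix.values.isna().to_numpy().any():
        raise ValueError("matrix contains missing values; run preprocess() first")
    return _de_table(
        matrix.values.to_numpy(float),
        matrix.values.index,
        matrix.group_columns("case"),
        matrix.group_columns("control"),
        fc_threshold,
        fdr_threshold,
    )


def selected_genes(de_table: pd.DataFrame) -> frozenset[str]:
    return frozenset(de_table.loc[de_table["selected"], "gene"])


def select_disease_genes(
    curated: Iterable[str],
    de_sets: Sequence[Iterable[str]],
    mode: str = "intersect",
) -> frozenset[str]:
    """Combine DE gene sets (intersect or union) and keep curated genes only."""
    if not de_sets:
        raise ValueError("at least one DE gene set is required")
    sets = [frozenset(s) for s in de_sets]
    if mode == "intersect":
        combined = frozenset.intersection(*sets)
    elif mode == "union":
        combined = frozenset.union(*sets)
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    return combined & frozenset(curated)


def bootstrap_overlap(
    matrix: ExpressionMatrix,
    curated: Iterable[str],
    n_boot: int = 100,
    seed: int | np.random.Generator = 0,
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.01,
    resample_fn: Callable[[np.random.Generator, np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Stability of the selected gene set under within-group resampling.

    Each replicate resamples samples with replacement within each group,
    recomputes the DE-and-curated gene set, and records
    ``|resampled set ∩ original set| / |original set|``.

    ``resample_fn(rng, column_indices) -> column_indices`` overrides the
    resampler (the identity function yields ratio 1.0 exactly).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    curated = frozenset(curated)
    values = matrix.values.to_numpy(float)
    genes = list(matrix.values.index)
    case_idx = matrix.group_columns("case")
    control_idx = matrix.group_columns("control")

    def gene_set(ci: np.ndarray, ni: np.ndarray) -> frozenset[str]:
        table = _de_table(values, genes, ci, ni, fc_threshold, fdr_threshold)
        return selected_genes(table) & curated

    original = gene_set(case_idx, control_idx)
    if not original:
        raise ValueError("original selected gene set is empty")
    if resample_fn is None:
        resample_fn = lambda r, idx: r.choice(idx, size=len(idx), replace=True)
    ratios = np.empty(n_boot)
    for b in range(n_boot):
        rep = gene_set(resample_fn(rng, case_idx), resample_fn(rng, control_idx))
        ratios[b] = len(rep & original) / len(original)
    return ratios
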