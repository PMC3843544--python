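"""Hypergeometric over-representation machinery.

A regulator with N targets in a universe of M genes, k of which are disease
(or annotated) genes, shows x targets overlapping the disease set. The
enrichment p-value is the hypergeometric upper tail

    P(X >= x),  X ~ Hypergeometric(M, k, N)

followed by Benjamini-Hochberg adjustment within the family of tests. The
same machinery backs regulator selection, random-gene-set validation of
hubs, mutated-gene-set tests, and functional-term enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts for one hypergeometric test.

    M: universe size; k: disease/annotated genes in the universe;
    N: size of the query (target) set; x: overlap of the query with the
    disease/annotated set.
    """

    M: int
    k: int
    N: int
    x: int

    def validate(self) -> None:
        if not (0 <= self.k <= self.M and 0 <= self.N <= self.M):
            raise ValueError(f"need 0 <= k,N <= M, got {self}")
        if not (0 <= self.x <= min(self.N, self.k)):
            raise ValueError(f"need 0 <= x <= min(N,k), got {self}")


def hypergeom_tail(input: EnrichmentInput | None = None, /, **kwargs) -> float:
    """Upper-tail probability ``P(X >= x)`` for the hypergeometric draw.

    Accepts either an :class:`EnrichmentInput` or keyword counts
    ``M, k, N, x``. Computed through scipy's log-scale survival function,
    so it is stable for large M. By definition the tail is 1 when x = 0.
    """
    if input is None:
        input = EnrichmentInput(**kwargs)
    input.validate()
    if input.x == 0:
        return 1.0
    return float(hypergeom.sf(input.x - 1, input.M, input.k, input.N))


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significant_regulators(
    target_map: Mapping[str, Iterable[str]],
    disease_genes: Iterable[str],
    M: int,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Test every regulator's target set for disease-gene enrichment.

    Returns one row per regulator with its counts, raw p, BH q over the
    supplied family of regulators, and the q < ``alpha`` significance flag.
    Regulators with empty target sets are skipped with a warning.
    """
    disease = frozenset(disease_genes)
    rows = []
    for regulator in sorted(target_map):
        targets = frozenset(target_map[regulator])
        if not targets:
            logger.warning("regulator %s has no targets; skipped", regulator)
            continue
        x = len(targets & disease)
        p = hypergeom_tail(EnrichmentInput(M=M, k=len(disease), N=len(targets), x=x))
        rows.append((regulator, len(targets), x, p))
    result = pd.DataFrame(rows, columns=["regulator", "n_targets", "overlap", "p_value"])
    result["q_value"] = bh_adjust(result["p_value"].to_numpy()) if len(result) else []
    result["significant"] = result["q_value"] < alpha
    return result


def random_geneset_validation(
    target_map: Mapping[str, Iterable[str]],
    universe: Sequence[str],
    set_size: int,
    reps: int,
    alpha: float = 0.01,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """Null significance frequency per regulator under random gene sets.

    Repeats the regulator enrichment ``reps`` times with gene sets drawn
    uniformly (size ``set_size``) from ``universe`` in place of the disease
    list, and reports how often each regulator is called significant.
    """
    if set_size > len(universe):
        raise ValueError("set_size exceeds the universe size")
    rng = np.random.default_rng(seed)
    universe = np.asarray(universe)
    hits: dict[str, int] = {r: 0 for r in target_map if target_map[r]}
    for _ in range(reps):
        random_set = rng.choice(universe, size=set_size, replace=False)
        table = significant_regulators(target_map, random_set, M=len(universe), alpha=alpha)
        for regulator in table.loc[table["significant"], "regulator"]:
            hits[regulator] += 1
    if reps == 0:
        return pd.Series(dtype=float, name="null_significance_frequency")
    freq = pd.Series({r: n / reps for r, n in hits.items()}, name="null_significance_frequency")
    return freq.sort_index()


def mutation_enrichment(
    motif_genes: Iterable[str],
    profile,
    rate_threshold: float = 0.05,
    M: int | None = None,
    subject: str = "motif_genes",
) -> pd.DataFrame:
    """Test a motif gene set against the highly mutated gene set.

    The mutated set is every profiled gene with per-sample mutation frequency
    strictly above ``rate_threshold``; the motif set (restricted to the
    universe) is then tested hypergeometrically. ``M`` defaults to the number
    of profiled genes.
    """
    universe = frozenset(profile.genes)
    if M is None:
        M = len(universe)
    mutated = profile.mutated_genes(rate_threshold)
    genes = frozenset(motif_genes) & universe
    x = len(genes & mutated)
    if not mutated:
        logger.warning("mutated gene set empty at threshold %s; p = 1", rate_threshold)
        p = 1.0
    else:
        p = hypergeom_tail(EnrichmentInput(M=M, k=len(mutated), N=len(genes), x=x))
    return pd.DataFrame(
        [
            {
                "subject": subject,
                "M": M,
                "k": len(mutated),
                "N": len(genes),
                "x": x,
                "p_value": p,
            }
        ]
    )
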