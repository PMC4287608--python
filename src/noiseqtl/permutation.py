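"""Structured whole-dataset permutation: the negative control for QTL counts.

Shuffling the line-to-sample assignment *within each randomized block*,
moving each complete multi-phenotype sample vector intact, destroys any
genotype-phenotype link while preserving every within-sample statistic —
in particular the phenotype x phenotype correlation structure that shared
technical or biological error would induce.  Re-deriving per-line CV and
mean from the permuted data and re-running the full QTL scan gives a null
distribution of genome-wide QTL counts; if structured error were driving
the observed QTL, permuted datasets would recover comparable counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cv import compute_line_cv
from .mapping import cim_scan, find_peaks, select_cofactors

__all__ = ["PermutationReport", "permute_links", "null_qtl_census"]


@dataclass(frozen=True)
class PermutationReport:
    """Null QTL-count census across structured permutations."""

    n_perm: int
    observed_count: int
    qtl_counts: tuple = ()  # per-permutation totals

    @property
    def max_count(self) -> int:
        return max(self.qtl_counts) if self.qtl_counts else 0

    @property
    def fraction(self) -> float:
        """Max null count relative to the observed count."""
        if self.observed_count == 0:
            return float("inf") if self.max_count else 0.0
        return self.max_count / self.observed_count

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "permutation": range(1, self.n_perm + 1),
                "qtl_count": list(self.qtl_counts),
                "observed_count": self.observed_count,
            }
        )


def permute_links(obs: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Randomize line-to-sample links within each block, vectors intact.

    Within every (experiment, block), the complete sample vectors (all
    phenotypes measured on one plant) are reassigned to lines by a uniform
    random permutation.  Genotypes are untouched; per-block sample
    multisets, and hence all per-sample statistics and cross-phenotype
    correlations, are preserved exactly.
    """
    required = {"line", "experiment", "block", "phenotype", "value"}
    if not required.issubset(obs.columns):
        raise KeyError(f"observations need columns {sorted(required)}")
    rng = np.random.default_rng(seed)
    all_lines = set(obs["line"].unique())
    out = []
    for (exp, block), sub in obs.groupby(["experiment", "block"], sort=True):
        counts = sub.groupby("line", sort=True)["phenotype"].count()
        if counts.nunique() > 1 or set(counts.index) != all_lines:
            raise ValueError(
                f"unequal sample sizes within block {block!r}: cannot permute vectors"
            )
        lines = list(counts.index)
        relabel = dict(zip(lines, [lines[i] for i in rng.permutation(len(lines))]))
        sub = sub.copy()
        sub["line"] = sub["line"].map(relabel)
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def null_qtl_census(
    obs: pd.DataFrame,
    grid,
    n_perm: int = 100,
    seed: int = 0,
    statistic: str = "mean_cv",
    lod_min: float = 2.0,
    k_cofactors: int = 3,
    window: float = 10.0,
    min_reps: int = 2,
) -> PermutationReport:
    """Observed vs permuted genome-wide significant-QTL counts.

    For the observed data and for each structured permutation: recompute
    per-line CV (or line means with ``statistic='grand_mean'``), scan every
    phenotype by composite interval mapping with forward-selected
    cofactors, and count peaks with LOD >= ``lod_min`` across all
    phenotypes.  Scan failures for individual phenotypes (e.g. degenerate
    CV columns) are skipped without aborting the census.
    """
    observed = _count_qtl(obs, grid, statistic, lod_min, k_cofactors, window, min_reps)
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(n_perm):
        perm = permute_links(obs, seed=int(rng.integers(2**31 - 1)))
        counts.append(
            _count_qtl(perm, grid, statistic, lod_min, k_cofactors, window, min_reps)
        )
    return PermutationReport(
        n_perm=n_perm, observed_count=observed, qtl_counts=tuple(counts)
    )


def _count_qtl(obs, grid, statistic, lod_min, k_cofactors, window, min_reps) -> int:
    table = compute_line_cv(obs, min_reps=min_reps)
    values = table.line_values(statistic)
    total = 0
    for phen in values.columns:
        y = values[phen]
        if y.notna().sum() < 10 or y.std() == 0:
            continue
        try:
            aligned = y.reindex(list(grid.lines))
            # mean-fill missing lines for cofactor selection only; the scan
            # itself drops them
            cofs = select_cofactors(grid, aligned.fillna(aligned.mean()).to_numpy(),
                                    k=k_cofactors)
            scan = cim_scan(grid, y, cofactors=cofs, window=window)
            total += len(find_peaks(scan, lod_min=lod_min))
        except (ValueError, np.linalg.LinAlgError):
            continue
    return total
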