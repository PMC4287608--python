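"""Per-line coefficient-of-variation phenotypes and population summaries.

The coefficient of variation (CV = sigma/mu) of replicate measurements of a
line within one experiment is treated as a phenotype in its own right: a
dimensionless measure of within-line stochastic noise.  Two independent
experiments give two biological replicate CV measures per line, whose mean
is the mapped phenotype.  Population-level statistics (the genetic
coefficient of variation across lines, percentile groupings, skewness and
kurtosis diagnostics, CV-vs-mean correlations) characterise how much
genetic variation the population holds for noise versus for the average
phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LineCVTable",
    "compute_line_cv",
    "population_genetic_cv",
    "classify_percentiles",
    "cv_mean_association",
    "distribution_diagnostics",
]

CLASS_LABELS = ("HIGH_CV_LOW_MEAN", "LOW_BOTH", "HIGH_MEAN_MID_CV", "NONE")


@dataclass(frozen=True)
class LineCVTable:
    """Per-(line, phenotype) CV and mean statistics.

    ``per_experiment``: long DataFrame (line, phenotype, experiment, n_reps,
    mean, cv, defined).  ``summary``: one row per (line, phenotype) with
    mean_cv (arithmetic mean of the defined per-experiment CVs), grand_mean
    (mean of all raw replicate values), and ``defined`` (any experiment
    defined).  Undefined entries are flagged, never silently zero.
    """

    per_experiment: pd.DataFrame
    summary: pd.DataFrame

    def line_values(self, statistic: str = "mean_cv") -> pd.DataFrame:
        """Line x phenotype matrix of a line-level statistic.

        ``statistic`` is ``"mean_cv"`` (the noise phenotype) or
        ``"grand_mean"`` (the average phenotype); undefined entries are NaN.
        """
        if statistic not in ("mean_cv", "grand_mean"):
            raise ValueError("statistic must be 'mean_cv' or 'grand_mean'")
        s = self.summary.copy()
        s.loc[~s["defined"], statistic] = np.nan
        return s.pivot(index="line", columns="phenotype", values=statistic)


def compute_line_cv(
    obs: pd.DataFrame,
    min_reps: int = 2,
    mean_floor: float | None = None,
) -> LineCVTable:
    """CV of the absolute replicate values per (line, experiment, phenotype).

    CV = sample SD (n-1 denominator) / mean, computed on ``abs(value)``
    separately for each experiment.  Entries with fewer than ``min_reps``
    replicates, or |mean| at or below ``mean_floor``, are flagged undefined.
    The default floor is 1e-12 times the largest absolute value of that
    phenotype, guarding against division by a near-zero mean.
    """
    if min_reps < 2:
        raise ValueError("min_reps must be >= 2")
    required = {"line", "experiment", "phenotype", "value"}
    if not required.issubset(obs.columns):
        raise KeyError(f"observations need columns {sorted(required)}")
    if not np.isfinite(obs["value"]).all():
        raise ValueError("observation values must be finite")

    df = obs.copy()
    df["value"] = df["value"].abs()
    if mean_floor is None:
        floors = df.groupby("phenotype")["value"].max() * 1e-12
    else:
        floors = pd.Series(mean_floor, index=df["phenotype"].unique())

    g = df.groupby(["line", "phenotype", "experiment"], sort=True)["value"]
    per = g.agg(n_reps="count", mean="mean", sd="std").reset_index()  # std is ddof=1
    per["defined"] = (per["n_reps"] >= min_reps) & (
        per["mean"].abs() > per["phenotype"].map(floors).to_numpy()
    )
    per["cv"] = np.where(per["defined"], per["sd"] / per["mean"], np.nan)
    per = per.drop(columns="sd")

    summary = (
        per.groupby(["line", "phenotype"], sort=True)["cv"]
        .mean()  # NaN (undefined) experiments are skipped; all-NaN -> NaN
        .rename("mean_cv")
        .reset_index()
    )
    grand = (
        df.groupby(["line", "phenotype"], sort=True)["value"]
        .mean()
        .rename("grand_mean")
        .reset_index()
    )
    summary = summary.merge(grand, on=["line", "phenotype"])
    summary["defined"] = summary["mean_cv"].notna()
    return LineCVTable(per_experiment=per, summary=summary)


def population_genetic_cv(table: LineCVTable, statistic: str = "mean_cv") -> pd.DataFrame:
    """Genetic coefficient of variation across the population, per phenotype.

    SD across lines divided by mean across lines of the chosen line-level
    statistic ("mean_cv" or "grand_mean").  Phenotypes with fewer than three
    defined lines are flagged undefined and excluded from downstream
    percentile ranking.
    """
    mat = table.line_values(statistic)
    n = mat.notna().sum(axis=0)
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    pop_cv = sd / mean
    out = pd.DataFrame(
        {
            "phenotype": mat.columns,
            "n_lines": n.to_numpy(),
            "mean": mean.to_numpy(),
            "sd": sd.to_numpy(),
            "population_cv": pop_cv.to_numpy(),
        }
    )
    out["defined"] = (out["n_lines"] >= 3) & np.isfinite(out["population_cv"])
    out.loc[~out["defined"], "population_cv"] = np.nan
    return out


def classify_percentiles(
    cv_of_cv: pd.DataFrame,
    cv_of_mean: pd.DataFrame,
    tail: float = 0.05,
) -> pd.Series:
    """Group phenotypes by where their population CVs fall in the tails.

    * HIGH_CV_LOW_MEAN — population CV of the noise phenotype in the top
      ``tail`` fraction AND population CV of the mean in the bottom tail
      (highly variable noise, constrained average);
    * LOW_BOTH — both in the bottom tail (robust metabolites);
    * HIGH_MEAN_MID_CV — population CV of the mean in the top tail while the
      noise statistic is in neither tail;
    * NONE — everything else.

    Ranks are computed over all phenotypes defined in both summaries; ties
    are broken by stable phenotype-id order.  Each tail holds
    floor(tail * n) phenotypes.
    """
    if not 0 < tail < 0.5:
        raise ValueError("tail must lie in (0, 0.5)")
    a = cv_of_cv.set_index("phenotype")["population_cv"]
    b = cv_of_mean.set_index("phenotype")["population_cv"]
    phen = sorted(set(a.dropna().index) & set(b.dropna().index))
    a, b = a[phen], b[phen]
    k = int(np.floor(tail * len(phen)))

    def _tails(s: pd.Series):
        order = s.reset_index().sort_values(
            ["population_cv", "phenotype"], kind="stable"
        )["phenotype"].tolist()
        return set(order[:k]), set(order[-k:] if k else [])

    low_a, high_a = _tails(a)
    low_b, high_b = _tails(b)
    labels = {}
    for p in phen:
        if p in high_a and p in low_b:
            labels[p] = "HIGH_CV_LOW_MEAN"
        elif p in low_a and p in low_b:
            labels[p] = "LOW_BOTH"
        elif p in high_b and p not in high_a and p not in low_a:
            labels[p] = "HIGH_MEAN_MID_CV"
        else:
            labels[p] = "NONE"
    return pd.Series(labels, name="class").rename_axis("phenotype")


def cv_mean_association(table: LineCVTable) -> pd.DataFrame:
    """Pearson and Spearman association between line CV and line mean.

    One row per phenotype (correlation across lines); zero-variance columns
    give an undefined (flagged) coefficient rather than zero.
    """
    cvm = table.line_values("mean_cv")
    mm = table.line_values("grand_mean")
    rows = []
    for p in cvm.columns:
        x, y = cvm[p], mm[p]
        ok = x.notna() & y.notna()
        x, y = x[ok].to_numpy(), y[ok].to_numpy()
        row = {"phenotype": p, "n": len(x), "defined": False,
               "pearson_r": np.nan, "pearson_p": np.nan,
               "spearman_r": np.nan, "spearman_p": np.nan}
        if len(x) >= 3 and np.std(x) > 0 and np.std(y) > 0:
            pr = stats.pearsonr(x, y)
            sr = stats.spearmanr(x, y)
            row.update(defined=True, pearson_r=pr.statistic, pearson_p=pr.pvalue,
                       spearman_r=sr.statistic, spearman_p=sr.pvalue)
        rows.append(row)
    return pd.DataFrame(rows)


def distribution_diagnostics(table: LineCVTable) -> pd.DataFrame:
    """Moment-based skewness and excess kurtosis across lines, per phenotype,
    for both the CV and the mean statistic (normality diagnostics)."""
    out = []
    for statistic in ("mean_cv", "grand_mean"):
        mat = table.line_values(statistic)
        for p in mat.columns:
            v = mat[p].dropna().to_numpy()
            defined = len(v) >= 4 and np.std(v) > 0
            out.append(
                {
                    "phenotype": p,
                    "statistic": statistic,
                    "n": len(v),
                    "defined": defined,
                    "skewness": stats.skew(v) if defined else np.nan,
                    "excess_kurtosis": stats.kurtosis(v) if defined else np.nan,
                }
            )
    return pd.DataFrame(out)
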