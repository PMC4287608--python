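"""Broad-sense heritability from a reciprocal-RIL variance decomposition.

In a reciprocal RIL population the maternally inherited organellar genomes
segregate as a single two-state factor, so phenotypic variance can be split
into an organellar (cytoplasm) component, a nuclear component (line nested
within cytoplasm), an experiment component, and residual:

    y_{cge} = mu + C_c + G_g(C_c) + E_e + eps

with one observation per line per experiment.  On balanced data the
components are extracted by equating observed mean squares to their
expectations (method of moments); broad-sense heritabilities are
H_nuclear = sigma2_G / sigma2_P and H_organellar = sigma2_C / sigma2_P with
sigma2_P the sum of all four components.  Negative moment estimates are
truncated to zero and flagged.  Unbalanced data fall back to REML
(statsmodels MixedLM variance components), which coincides with the moment
estimates in the balanced limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["HeritabilityResult", "fit_heritability", "heritability_from_cv_table"]


@dataclass(frozen=True)
class HeritabilityResult:
    """Variance components and heritabilities for one phenotype."""

    var_cyto: float
    var_line: float
    var_experiment: float
    var_residual: float
    h2_nuclear: float
    h2_organellar: float
    p_values: dict = field(default_factory=dict)  # term -> F-test p
    truncated: tuple = ()  # components clipped at zero
    method: str = "ems"  # "ems" (expected mean squares) or "reml"
    degenerate: bool = False

    @property
    def var_phenotypic(self) -> float:
        return self.var_cyto + self.var_line + self.var_experiment + self.var_residual


def _is_balanced(df: pd.DataFrame) -> bool:
    counts = df.groupby(["line", "experiment"], observed=True).size()
    if counts.nunique() != 1:
        return False
    n_exp = df["experiment"].nunique()
    per_line = df.groupby("line", observed=True)["experiment"].nunique()
    return bool((per_line == n_exp).all())


def fit_heritability(
    values: pd.DataFrame,
    cytoplasm: pd.Series,
    include_experiment_in_total: bool = True,
) -> HeritabilityResult:
    """Fit the line-heritability model to long data (line, experiment, value).

    ``cytoplasm`` maps every line to its organellar class.  Balanced data
    (every line in every experiment, equal replication) use closed-form
    expected-mean-squares estimation with F-tests per term: cytoplasm is
    tested against the line-within-cytoplasm mean square, line and
    experiment against residual.  Unbalanced data trigger a REML fallback
    with a warning.  ``include_experiment_in_total=False`` drops the
    experiment component from sigma2_P.
    """
    df = values[["line", "experiment", "value"]].dropna().copy()
    if df.empty:
        raise ValueError("no observations")
    missing = set(df["line"]) - set(cytoplasm.index)
    if missing:
        raise KeyError(f"lines without a cytoplasm label: {sorted(missing)[:5]}")
    df["cyto"] = df["line"].map(cytoplasm)

    n_exp = df["experiment"].nunique()
    if n_exp < 2:
        warnings.warn("single experiment: sigma2_E not estimable, set to 0")
    if np.allclose(df["value"], df["value"].iloc[0]):
        return HeritabilityResult(
            0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
            p_values={}, truncated=(), method="ems", degenerate=True,
        )

    if _is_balanced(df) and df.groupby(["line", "experiment"]).size().iloc[0] == 1:
        res = _fit_ems(df)
    else:
        warnings.warn("unbalanced design: falling back to REML variance components")
        res = _fit_reml(df)

    vc, vg, ve, vr, pvals, trunc, method = res
    total = vc + vg + vr + (ve if include_experiment_in_total else 0.0)
    if total <= 0:
        h2n = h2o = 0.0
        degenerate = True
    else:
        h2n, h2o, degenerate = vg / total, vc / total, False
    return HeritabilityResult(
        var_cyto=vc, var_line=vg, var_experiment=ve, var_residual=vr,
        h2_nuclear=h2n, h2_organellar=h2o,
        p_values=pvals, truncated=tuple(trunc), method=method, degenerate=degenerate,
    )


def _fit_ems(df: pd.DataFrame):
    """Balanced-case method of moments with one observation per line x experiment."""
    y = df["value"].to_numpy()
    grand = y.mean()
    e = df["experiment"].nunique()
    line_means = df.groupby("line", observed=True)["value"].mean()
    cyto_of_line = df.drop_duplicates("line").set_index("line")["cyto"]
    n_lines = len(line_means)
    classes = cyto_of_line.groupby(cyto_of_line).groups  # class -> line ids
    n_i = {c: len(ix) for c, ix in classes.items()}
    n_classes = len(n_i)

    class_means = {c: line_means[list(ix)].mean() for c, ix in classes.items()}
    exp_means = df.groupby("experiment", observed=True)["value"].mean()

    ss_c = e * sum(n_i[c] * (class_means[c] - grand) ** 2 for c in classes)
    ss_g = e * sum(
        ((line_means[list(ix)] - class_means[c]) ** 2).sum() for c, ix in classes.items()
    )
    ss_e = n_lines * ((exp_means - grand) ** 2).sum()
    ss_tot = ((y - grand) ** 2).sum()
    ss_r = ss_tot - ss_c - ss_g - ss_e

    df_c = n_classes - 1
    df_g = n_lines - n_classes
    df_e = e - 1
    # C and G(C) exhaust the between-line df, so residual df is the remainder
    df_r = len(y) - 1 - df_c - df_g - df_e

    ms = {
        "cytoplasm": ss_c / df_c if df_c else np.nan,
        "line": ss_g / df_g,
        "experiment": ss_e / df_e if df_e else np.nan,
        "residual": ss_r / df_r,
    }
    # EMS coefficients: E[MS_G] = s2r + e*s2G; E[MS_E] = s2r + n_lines*s2E;
    # E[MS_C] = s2r + e*s2G + e*n0*s2C with the unequal-class-size n0.
    N = n_lines
    n0 = (N - sum(v * v for v in n_i.values()) / N) / df_c if df_c else np.nan

    trunc = []
    vr = ms["residual"]
    vg = (ms["line"] - vr) / e
    ve = (ms["experiment"] - vr) / N if df_e else 0.0
    vc = (ms["cytoplasm"] - ms["line"]) / (e * n0) if df_c else 0.0
    out = {}
    for name, v in (("cytoplasm", vc), ("line", vg), ("experiment", ve), ("residual", vr)):
        if v < 0:
            trunc.append(name)
            v = 0.0
        out[name] = v

    pvals = {}
    if df_c:
        f = ms["cytoplasm"] / ms["line"]
        pvals["cytoplasm"] = float(stats.f.sf(f, df_c, df_g))
    f = ms["line"] / ms["residual"]
    pvals["line"] = float(stats.f.sf(f, df_g, df_r))
    if df_e:
        f = ms["experiment"] / ms["residual"]
        pvals["experiment"] = float(stats.f.sf(f, df_e, df_r))

    return (out["cytoplasm"], out["line"], out["experiment"], out["residual"],
            pvals, trunc, "ems")


def _fit_reml(df: pd.DataFrame):
    """REML variance components via MixedLM with a single grouping."""
    import statsmodels.formula.api as smf

    d = df.copy()
    d["grp"] = 1
    vc_formula = {"cyto": "0 + C(cyto)", "line": "0 + C(line)"}
    if d["experiment"].nunique() > 1:
        vc_formula["experiment"] = "0 + C(experiment)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("value ~ 1", data=d, groups="grp", vc_formula=vc_formula)
        fit = model.fit(reml=True)
    vcomp = dict(zip(model.exog_vc.names, np.asarray(fit.vcomp)))
    vr = float(fit.scale)
    vc = float(vcomp.get("cyto", 0.0))
    vg = float(vcomp.get("line", 0.0))
    ve = float(vcomp.get("experiment", 0.0))
    trunc = [k for k, v in (("cytoplasm", vc), ("line", vg), ("experiment", ve)) if v <= 0]
    return (max(vc, 0.0), max(vg, 0.0), max(ve, 0.0), vr, {}, trunc, "reml")


def heritability_from_cv_table(
    table,
    cytoplasm: pd.Series,
    phenotype: str,
    statistic: str = "cv",
) -> HeritabilityResult:
    """Heritability of per-experiment CV (``statistic='cv'``) or of the
    per-experiment line mean (``'mean'``) for one phenotype of a LineCVTable."""
    per = table.per_experiment
    sub = per[(per["phenotype"] == phenotype)]
    if sub.empty:
        raise KeyError(f"phenotype {phenotype!r} not in table")
    col = {"cv": "cv", "mean": "mean"}[statistic]
    vals = sub.loc[sub["defined"], ["line", "experiment", col]].rename(
        columns={col: "value"}
    )
    return fit_heritability(vals, cytoplasm)
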