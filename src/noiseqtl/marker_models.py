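"""Hotspot-marker ANOVA models: additive effects, pairwise epistasis, networks.

After hotspot detection, the genotyped marker nearest each hotspot (plus
the cytoplasm as one extra single-locus marker) enters fixed-effect linear
models per phenotype:

* additive model — all markers as main effects;
* pairwise epistasis model — all main effects plus every pairwise
  marker x marker product (cytoplasm included), with no three-way terms.

Each term is assessed with Type III sums of squares and an F-test;
Benjamini-Hochberg FDR is applied across the terms of one model for one
phenotype.  Across phenotypes, a locus's main-effect "breadth" is the
fraction of phenotypes where it is significant (q < 0.05), and locus-pair
interaction breadths build an epistasis network in which edges below a
minimum breadth (default 10% of phenotypes) are excluded as an additional
multiple-testing control.

With fully inbred biallelic markers coded -1/+1 and balanced classes, the
design is (near-)orthogonal and Type III equals sequential sums of squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MarkerModelResult",
    "additive_anova",
    "pairwise_epistasis_anova",
    "build_network",
    "interactions_per_locus",
    "network_to_sif",
]

CYTOPLASM = "CYTOPLASM"


@dataclass(frozen=True)
class MarkerModelResult:
    """Per-term Type III ANOVA results for one phenotype.

    ``table`` columns: term, kind ("main"/"interaction"), ss, df, F, p, q,
    effect (allelic substitution = difference between class-adjusted means,
    i.e. twice the -1/+1 regression coefficient; NaN for interactions of
    untestable pairs), testable.
    """

    phenotype: str
    table: pd.DataFrame
    rss: float
    df_resid: int
    dropped: tuple = ()  # confounded markers removed
    skipped_pairs: tuple = ()  # pairs with an empty 2x2 genotype cell


def _prepare_markers(markers: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Validate -1/+1 coding and drop duplicated (confounded) columns."""
    M = markers.astype(float)
    if not np.isin(M.to_numpy(), [-1.0, 1.0]).all():
        raise ValueError("marker codes must be -1/+1 (use RILGenotypes.signed())")
    dropped = []
    seen: dict[bytes, str] = {}
    keep = []
    for col in M.columns:
        key = M[col].to_numpy().tobytes()
        key_flip = (-M[col].to_numpy()).tobytes()
        if key in seen or key_flip in seen:
            dropped.append(col)
            warnings.warn(f"marker {col!r} confounded with {seen.get(key, seen.get(key_flip))!r}; dropped")
        else:
            seen[key] = col
            keep.append(col)
    return M[keep], dropped


def _type3_anova(y: np.ndarray, columns: dict, phenotype: str,
                 dropped=(), skipped=()) -> MarkerModelResult:
    """Shared Type III machinery: ``columns`` maps term -> regressor column."""
    n = len(y)
    names = list(columns)
    X = np.column_stack([np.ones(n)] + [columns[t] for t in names])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df_resid = n - rank
    rows = []
    for j, term in enumerate(names):
        Xr = np.delete(X, j + 1, axis=1)
        br, *_ = np.linalg.lstsq(Xr, y, rcond=None)
        rr = y - Xr @ br
        ss = max(float(rr @ rr) - rss, 0.0)
        if df_resid > 0 and rss > 0:
            F = ss / (rss / df_resid)
            p = float(stats.f.sf(F, 1, df_resid))
        elif ss == 0.0:
            F, p = 0.0, 1.0
        else:
            F, p = np.inf, 0.0
        rows.append(
            {
                "term": term,
                "kind": "interaction" if ":" in term else "main",
                "ss": ss,
                "df": 1,
                "F": F,
                "p": p,
                "effect": 2.0 * beta[j + 1],
                "testable": True,
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    return MarkerModelResult(
        phenotype=phenotype, table=table, rss=rss, df_resid=df_resid,
        dropped=tuple(dropped), skipped_pairs=tuple(skipped),
    )


def additive_anova(
    phenotype: pd.Series,
    markers: pd.DataFrame,
    phenotype_name: str | None = None,
) -> MarkerModelResult:
    """All-markers main-effect model for one line-level phenotype.

    ``markers`` is a line x marker DataFrame coded -1/+1 (include a
    CYTOPLASM column to test organellar effects); ``phenotype`` is indexed
    by line.  Requires >= 2 lines per genotype class at every marker.
    """
    y, M = _align(phenotype, markers)
    M, dropped = _prepare_markers(M)
    for col in M.columns:
        counts = M[col].value_counts()
        if counts.min() < 2 or len(counts) < 2:
            raise ValueError(f"marker {col!r} lacks 2 lines per genotype class")
    cols = {c: M[c].to_numpy() for c in M.columns}
    return _type3_anova(y, cols, phenotype_name or getattr(phenotype, "name", "") or "",
                        dropped=dropped)


def pairwise_epistasis_anova(
    phenotype: pd.Series,
    markers: pd.DataFrame,
    phenotype_name: str | None = None,
) -> MarkerModelResult:
    """Main effects plus all pairwise marker x marker interaction terms.

    Interaction terms are products of the -1/+1 codes; pairs with an empty
    2x2 genotype cell are skipped (logged on the result).  BH FDR is
    applied across all terms of the model.  No three-way terms are fitted.
    """
    y, M = _align(phenotype, markers)
    M, dropped = _prepare_markers(M)
    cols: dict[str, np.ndarray] = {c: M[c].to_numpy() for c in M.columns}
    skipped = []
    for a, b in combinations(M.columns, 2):
        cells = pd.crosstab(M[a], M[b])
        if cells.shape != (2, 2) or (cells.to_numpy() == 0).any():
            skipped.append((a, b))
            continue
        cols[f"{a}:{b}"] = M[a].to_numpy() * M[b].to_numpy()
    return _type3_anova(y, cols, phenotype_name or getattr(phenotype, "name", "") or "",
                        dropped=dropped, skipped=skipped)


def _align(phenotype: pd.Series, markers: pd.DataFrame):
    common = markers.index.intersection(phenotype.dropna().index)
    if len(common) < len(markers.columns) + 2:
        raise ValueError("too few lines for the marker model")
    return phenotype.loc[common].to_numpy(dtype=float), markers.loc[common]


def build_network(
    results: list[MarkerModelResult],
    edge_min: float = 0.10,
    q_max: float = 0.05,
) -> nx.Graph:
    """Epistasis network over loci from per-phenotype model results.

    Node breadth = fraction of phenotypes with a significant (q < ``q_max``)
    main effect; edge breadth = fraction with a significant interaction.
    Edges with breadth below ``edge_min`` are dropped (breadth exactly at
    the boundary is retained).
    """
    if not results:
        raise ValueError("no model results")
    n_phen = len(results)
    main_hits: dict[str, int] = {}
    pair_hits: dict[tuple, int] = {}
    nodes: set[str] = set()
    for res in results:
        t = res.table
        for _, row in t.iterrows():
            if row["kind"] == "main":
                nodes.add(row["term"])
                if row["q"] < q_max:
                    main_hits[row["term"]] = main_hits.get(row["term"], 0) + 1
            else:
                a, b = row["term"].split(":")
                if row["q"] < q_max:
                    key = tuple(sorted((a, b)))
                    pair_hits[key] = pair_hits.get(key, 0) + 1
    g = nx.Graph()
    for node in sorted(nodes):
        g.add_node(node, breadth=main_hits.get(node, 0) / n_phen)
    for (a, b), hits in sorted(pair_hits.items()):
        breadth = hits / n_phen
        if breadth >= edge_min:
            g.add_edge(a, b, breadth=breadth)
    return g


def interactions_per_locus(network: nx.Graph) -> pd.DataFrame:
    """Degree (number of epistatic partners) per locus, with the median
    attached as ``median_interactions`` on every row."""
    rows = [
        {"locus": node, "interactions": network.degree(node),
         "breadth": network.nodes[node].get("breadth", np.nan)}
        for node in sorted(network.nodes)
    ]
    out = pd.DataFrame(rows, columns=["locus", "interactions", "breadth"])
    out["median_interactions"] = out["interactions"].median() if len(out) else np.nan
    return out


def network_to_sif(network: nx.Graph, path) -> None:
    """Write the network as SIF (``locus1 epistasis locus2`` lines)."""
    with open(path, "w") as fh:
        for a, b in sorted(network.edges):
            fh.write(f"{a}\tepistasis\t{b}\n")
        for node in sorted(nx.isolates(network)):
            fh.write(f"{node}\n")
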