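"""File formats: map TSV, genotype TSV, long phenotype CSV, truth YAML.

All tables are plain text with explicit headers:

* map TSV — columns ``chromosome``, ``marker``, ``cm``;
* genotype TSV — ``line``, ``cytoplasm``, then one column per marker with
  codes A/B;
* phenotype CSV — long format ``line``, ``experiment``, ``block``,
  ``phenotype``, ``value``;
* truth YAML — the simulator's ground-truth architecture, for
  parameter-recovery checks.
"""

from __future__ import annotations

import dataclasses

import pandas as pd
import yaml

from .simulate import (
    EpistaticPair,
    GeneticMap,
    QTLEffect,
    RILGenotypes,
    TrueArchitecture,
)

__all__ = [
    "write_map", "read_map",
    "write_genotypes", "read_genotypes",
    "write_phenotypes", "read_phenotypes",
    "write_truth", "read_truth",
    "read_supplementary_xlsx",
]


def write_map(gmap: GeneticMap, path) -> None:
    gmap.table.to_csv(path, sep="\t", index=False)


def read_map(path) -> GeneticMap:
    return GeneticMap(pd.read_csv(path, sep="\t"))


def write_genotypes(geno: RILGenotypes, path) -> None:
    out = geno.alleles.copy()
    out.insert(0, "cytoplasm", geno.cytoplasm)
    out.index.name = "line"
    out.to_csv(path, sep="\t")


def read_genotypes(path) -> RILGenotypes:
    df = pd.read_csv(path, sep="\t", index_col="line")
    cyto = df.pop("cytoplasm")
    return RILGenotypes(alleles=df, cytoplasm=cyto)


def write_phenotypes(obs: pd.DataFrame, path) -> None:
    obs[["line", "experiment", "block", "phenotype", "value"]].to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truth(arch: TrueArchitecture, path) -> None:
    doc = dataclasses.asdict(arch)
    doc["traits"] = list(doc["traits"])
    doc["mean_qtl"] = [_qtl_doc(q) for q in arch.mean_qtl]
    doc["var_qtl"] = [_qtl_doc(q) for q in arch.var_qtl]
    doc["epistatic_pairs"] = [
        {
            "locus1": list(p.locus1),
            "locus2": list(p.locus2),
            "effect": p.effect,
            "traits": list(p.traits) if p.traits is not None else None,
        }
        for p in arch.epistatic_pairs
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(_pythonize(doc), fh, sort_keys=False)


def _pythonize(obj):
    """Coerce numpy scalars (and tuples) to plain Python for YAML."""
    if isinstance(obj, dict):
        return {_pythonize(k): _pythonize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pythonize(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def _qtl_doc(q: QTLEffect) -> dict:
    return {
        "chromosome": q.chromosome,
        "position_cm": q.position_cm,
        "effect": q.effect,
        "traits": list(q.traits) if q.traits is not None else None,
    }


def read_truth(path) -> TrueArchitecture:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    def _tup(x):
        return tuple(x) if x is not None else None
    return TrueArchitecture(
        traits=tuple(doc["traits"]),
        grand_mean=doc["grand_mean"],
        base_sd=doc["base_sd"],
        mean_qtl=tuple(
            QTLEffect(d["chromosome"], d["position_cm"], d["effect"], _tup(d["traits"]))
            for d in doc["mean_qtl"]
        ),
        var_qtl=tuple(
            QTLEffect(d["chromosome"], d["position_cm"], d["effect"], _tup(d["traits"]))
            for d in doc["var_qtl"]
        ),
        cyto_mean_effect=doc["cyto_mean_effect"],
        cyto_sd_effect=doc["cyto_sd_effect"],
        epistatic_pairs=tuple(
            EpistaticPair(tuple(d["locus1"]), tuple(d["locus2"]), d["effect"],
                          _tup(d["traits"]))
            for d in doc["epistatic_pairs"]
        ),
        experiment_effects=doc["experiment_effects"],
        block_effects=doc["block_effects"],
        distribution=doc.get("distribution", "normal"),
    )


def read_supplementary_xlsx(path, sheet_name=0) -> pd.DataFrame:
    """Load a supplementary XLSX table (per-line CV or QTL tables) for
    spot-check scripts; a thin wrapper over pandas' openpyxl engine."""
    return pd.read_excel(path, sheet_name=sheet_name, engine="openpyxl")
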