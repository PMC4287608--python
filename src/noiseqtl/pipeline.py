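"""End-to-end pipeline: simulate -> CV -> heritability -> scans -> hotspots
-> marker ANOVA -> structured-permutation null census.

One YAML config (validated by a pydantic schema) drives every stage; one
root seed expands deterministically into per-stage seeds.  Each stage
writes plain-text tables into the output directory and records parameters,
seeds, output hashes, and wall-clock in a JSON manifest, so every table is
re-derivable from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import cv as cv_mod
from . import heritability as herit_mod
from . import hotspots as hot_mod
from . import io as io_mod
from . import mapping as map_mod
from . import marker_models as mm_mod
from . import permutation as perm_mod
from . import simulate as sim_mod

logger = logging.getLogger("noiseqtl")

__all__ = ["RunConfig", "run_pipeline", "summarize_run", "stage_seeds"]


class SimulateConfig(BaseModel):
    enabled: bool = True
    n_lines: int = 316
    n_experiments: int = 2
    reps_per_experiment: int = 2
    n_chromosomes: int = 5
    chrom_length: float = 90.0
    marker_spacing: float = 5.0
    n_metabolites: int = 60
    n_defense: int = 8
    n_growth: int = 3
    distribution: str = "normal"


class InputConfig(BaseModel):
    map: str | None = None
    genotypes: str | None = None
    phenotypes: str | None = None


class CVConfig(BaseModel):
    enabled: bool = True
    min_reps: int = 2
    tail: float = 0.05
    mean_floor: float | None = None


class HeritabilityConfig(BaseModel):
    enabled: bool = True


class ScanConfig(BaseModel):
    enabled: bool = True
    phenotype_sets: list[str] = Field(default_factory=lambda: ["cv", "mean"])
    cofactors: int = 3
    window: float = 10.0
    step: float = 1.0
    n_perm: int = 0  # per-trait permutation thresholds (0 = skip, use lod_min)
    alpha: float = 0.05
    lod_min: float = 2.0


class HotspotConfig(BaseModel):
    enabled: bool = True
    window: float = 5.0
    step: float = 1.0
    alpha: float = 0.05
    n_perm: int = 1000
    prefix: str = "M"


class AnovaConfig(BaseModel):
    enabled: bool = True
    edge_min: float = 0.10
    fdr: float = 0.05


class NullCensusConfig(BaseModel):
    enabled: bool = False
    n_perm: int = 10


class RunConfig(BaseModel):
    out_dir: str = "noiseqtl_run"
    seed: int = 0
    simulate: SimulateConfig = SimulateConfig()
    inputs: InputConfig = InputConfig()
    cv: CVConfig = CVConfig()
    heritability: HeritabilityConfig = HeritabilityConfig()
    scan: ScanConfig = ScanConfig()
    hotspots: HotspotConfig = HotspotConfig()
    anova: AnovaConfig = AnovaConfig()
    null_census: NullCensusConfig = NullCensusConfig()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.model_validate(doc)


STAGES = ("simulate", "cv", "heritability", "scan", "hotspots", "anova", "null_census")


def stage_seeds(root_seed: int) -> dict:
    """Expand one root seed into independent per-stage seeds (< 2^31)."""
    ss = np.random.SeedSequence(root_seed)
    state = ss.generate_state(len(STAGES), dtype=np.uint64)
    return {name: int(s % (2**31 - 1)) for name, s in zip(STAGES, state)}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages in order; returns the manifest dict.

    A disabled stage whose outputs are required downstream must already
    have its files in ``out_dir`` (from a previous run); otherwise the
    dependent stage fails fast with a stage-tagged error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest: dict = {"root_seed": config.seed, "stages": {}, "started_at": time.time()}
    state: dict = {}

    def record(stage: str, params: dict, t0: float, files: list[Path]):
        manifest["stages"][stage] = {
            "params": params,
            "seed": seeds[stage],
            "wall_clock_s": round(time.time() - t0, 3),
            "outputs": {f.name: _sha256(f) for f in files},
        }

    # --- simulate -----------------------------------------------------
    if config.simulate.enabled:
        t0 = time.time()
        logger.info("stage simulate: %d lines", config.simulate.n_lines)
        sc = config.simulate
        gmap = sim_mod.build_default_map(sc.n_chromosomes, sc.chrom_length, sc.marker_spacing)
        design = sim_mod.DesignSpec(
            n_lines=sc.n_lines, n_experiments=sc.n_experiments,
            reps_per_experiment=sc.reps_per_experiment, seed=seeds["simulate"],
        )
        geno = sim_mod.simulate_ril_genotypes(gmap, design)
        arch = sim_mod.default_architecture(
            gmap, n_metabolites=sc.n_metabolites, n_defense=sc.n_defense,
            n_growth=sc.n_growth, seed=seeds["simulate"],
        )
        if sc.distribution != "normal":
            arch = sim_mod.TrueArchitecture(
                **{**arch.__dict__, "distribution": sc.distribution}
            )
        obs = sim_mod.simulate_phenotypes(geno, arch, design, gmap)
        io_mod.write_map(gmap, out / "map.tsv")
        io_mod.write_genotypes(geno, out / "genotypes.tsv")
        io_mod.write_phenotypes(obs, out / "phenotypes.csv")
        io_mod.write_truth(arch, out / "truth.yaml")
        state.update(gmap=gmap, geno=geno, obs=obs, arch=arch)
        record("simulate", sc.model_dump(), t0,
               [out / f for f in ("map.tsv", "genotypes.tsv", "phenotypes.csv", "truth.yaml")])
    else:
        _load_inputs(config, out, state)

    # --- cv -----------------------------------------------------------
    if config.cv.enabled:
        t0 = time.time()
        _require(state, "obs", "cv", "phenotype observations")
        logger.info("stage cv")
        table = cv_mod.compute_line_cv(
            state["obs"], min_reps=config.cv.min_reps, mean_floor=config.cv.mean_floor
        )
        pop_cv = cv_mod.population_genetic_cv(table, "mean_cv")
        pop_mean = cv_mod.population_genetic_cv(table, "grand_mean")
        labels = cv_mod.classify_percentiles(pop_cv, pop_mean, tail=config.cv.tail)
        summary = pop_cv.rename(columns={"population_cv": "population_cv_of_cv"}).merge(
            pop_mean[["phenotype", "population_cv"]].rename(
                columns={"population_cv": "population_cv_of_mean"}
            ),
            on="phenotype",
        )
        summary = summary.merge(labels.reset_index(), on="phenotype", how="left")
        table.summary.to_csv(out / "line_cv.csv", index=False)
        summary.to_csv(out / "population_summary.csv", index=False)
        state.update(cv_table=table, population_summary=summary)
        record("cv", config.cv.model_dump(), t0,
               [out / "line_cv.csv", out / "population_summary.csv"])

    # --- heritability ---------------------------------------------------
    if config.heritability.enabled:
        t0 = time.time()
        _require(state, "cv_table", "heritability", "the cv stage")
        _require(state, "geno", "heritability", "genotypes")
        logger.info("stage heritability")
        rows = []
        cyto = state["geno"].cytoplasm
        for phen in sorted(state["cv_table"].summary["phenotype"].unique()):
            for statistic in ("cv", "mean"):
                try:
                    r = herit_mod.heritability_from_cv_table(
                        state["cv_table"], cyto, phen, statistic
                    )
                except (ValueError, KeyError):
                    continue
                rows.append(
                    {
                        "phenotype": phen, "statistic": statistic,
                        "var_cyto": r.var_cyto, "var_line": r.var_line,
                        "var_experiment": r.var_experiment, "var_residual": r.var_residual,
                        "h2_nuclear": r.h2_nuclear, "h2_organellar": r.h2_organellar,
                        "p_cytoplasm": r.p_values.get("cytoplasm", np.nan),
                        "p_line": r.p_values.get("line", np.nan),
                        "p_experiment": r.p_values.get("experiment", np.nan),
                        "truncated": ";".join(r.truncated), "method": r.method,
                        "degenerate": r.degenerate,
                    }
                )
        herit = pd.DataFrame(rows)
        herit.to_csv(out / "heritability.csv", index=False)
        state["heritability"] = herit
        record("heritability", {}, t0, [out / "heritability.csv"])

    # --- scan -----------------------------------------------------------
    if config.scan.enabled:
        t0 = time.time()
        for key in ("gmap", "geno", "cv_table"):
            _require(state, key, "scan", key)
        sc = config.scan
        logger.info("stage scan: sets=%s", sc.phenotype_sets)
        grid = map_mod.genotype_probabilities(state["gmap"], state["geno"], step=sc.step)
        state["grid"] = grid
        rng = np.random.default_rng(seeds["scan"])
        files = []
        for pset in sc.phenotype_sets:
            statistic = {"cv": "mean_cv", "mean": "grand_mean"}[pset]
            values = state["cv_table"].line_values(statistic)
            scans, peaks = [], {}
            for phen in values.columns:
                y = values[phen]
                if y.notna().sum() < 10 or np.nanstd(y.to_numpy()) == 0:
                    continue
                aligned = y.reindex(list(grid.lines))
                cofs = map_mod.select_cofactors(
                    grid, aligned.fillna(aligned.mean()).to_numpy(), k=sc.cofactors
                )
                scan = map_mod.cim_scan(grid, y, cofactors=cofs, window=sc.window)
                lod_min = sc.lod_min
                threshold = np.nan
                if sc.n_perm > 0:
                    threshold = map_mod.permutation_threshold(
                        grid, y, n_perm=sc.n_perm, alpha=sc.alpha,
                        seed=int(rng.integers(2**31 - 1)), k_cofactors=sc.cofactors,
                        window=sc.window,
                    )
                trait_mean = float(values[phen].mean())
                found = map_mod.find_peaks(
                    scan, lod_min=lod_min,
                    trait_mean=trait_mean if trait_mean != 0 else None,
                )
                st = scan.table.copy()
                st.insert(0, "phenotype", phen)
                st["perm_threshold"] = threshold
                scans.append(st)
                peaks[phen] = found
            scan_table = pd.concat(scans, ignore_index=True) if scans else pd.DataFrame()
            peak_table = map_mod.peaks_to_table(peaks)
            scan_table.to_csv(out / f"scan_{pset}.csv", index=False)
            peak_table.to_csv(out / f"peaks_{pset}.csv", index=False)
            files += [out / f"scan_{pset}.csv", out / f"peaks_{pset}.csv"]
            state[f"peaks_{pset}"] = peak_table
        record("scan", sc.model_dump(), t0, files)

    # --- hotspots --------------------------------------------------------
    if config.hotspots.enabled:
        t0 = time.time()
        _require(state, "gmap", "hotspots", "the map")
        hc = config.hotspots
        files = []
        rng = np.random.default_rng(seeds["hotspots"])
        for pset in config.scan.phenotype_sets:
            _require(state, f"peaks_{pset}", "hotspots", f"scan[{pset}] peaks")
            peaks = state[f"peaks_{pset}"]
            profile = hot_mod.window_counts(peaks, state["gmap"], hc.window, hc.step)
            if len(peaks):
                thr = hot_mod.hotspot_threshold(
                    peaks, state["gmap"], hc.window, hc.step,
                    n_perm=hc.n_perm, alpha=hc.alpha,
                    seed=int(rng.integers(2**31 - 1)),
                )
                prefix = f"{hc.prefix}.{pset.upper()}"
                profile = hot_mod.name_hotspots(profile, thr, prefix)
            profile.counts.to_csv(out / f"hotspot_counts_{pset}.csv", index=False)
            hs = profile.hotspots if profile.hotspots is not None else pd.DataFrame(
                columns=["name", "chromosome", "cm", "count"]
            )
            hs.to_csv(out / f"hotspots_{pset}.csv", index=False)
            files += [out / f"hotspot_counts_{pset}.csv", out / f"hotspots_{pset}.csv"]
            state[f"hotspots_{pset}"] = hs
        record("hotspots", hc.model_dump(), t0, files)

    # --- anova -----------------------------------------------------------
    if config.anova.enabled:
        t0 = time.time()
        for key in ("gmap", "geno", "cv_table"):
            _require(state, key, "anova", key)
        ac = config.anova
        files = []
        for pset in config.scan.phenotype_sets:
            _require(state, f"hotspots_{pset}", "anova", f"hotspots[{pset}]")
            hs = state[f"hotspots_{pset}"]
            markers = _hotspot_markers(state["gmap"], state["geno"], hs)
            statistic = {"cv": "mean_cv", "mean": "grand_mean"}[pset]
            values = state["cv_table"].line_values(statistic)
            results = []
            add_rows, epi_rows = [], []
            for phen in values.columns:
                y = values[phen].dropna()
                if len(y) < len(markers.columns) + 3 or y.std() == 0:
                    continue
                try:
                    add = mm_mod.additive_anova(y, markers, phenotype_name=phen)
                    epi = mm_mod.pairwise_epistasis_anova(y, markers, phenotype_name=phen)
                except ValueError:
                    continue
                results.append(epi)
                add_rows.append(add.table.assign(phenotype=phen))
                epi_rows.append(epi.table.assign(phenotype=phen))
            _concat_to(add_rows, out / f"anova_additive_{pset}.csv")
            _concat_to(epi_rows, out / f"anova_epistasis_{pset}.csv")
            files += [out / f"anova_additive_{pset}.csv", out / f"anova_epistasis_{pset}.csv"]
            if results:
                net = mm_mod.build_network(results, edge_min=ac.edge_min, q_max=ac.fdr)
                mm_mod.network_to_sif(net, out / f"network_{pset}.sif")
                deg = mm_mod.interactions_per_locus(net)
                deg.to_csv(out / f"network_nodes_{pset}.csv", index=False)
                files += [out / f"network_{pset}.sif", out / f"network_nodes_{pset}.csv"]
                state[f"network_{pset}"] = net
        record("anova", ac.model_dump(), t0, files)

    # --- null census ------------------------------------------------------
    if config.null_census.enabled:
        t0 = time.time()
        for key in ("obs", "grid"):
            _require(state, key, "null_census", key)
        nc = config.null_census
        report = perm_mod.null_qtl_census(
            state["obs"], state["grid"], n_perm=nc.n_perm, seed=seeds["null_census"],
            lod_min=config.scan.lod_min, k_cofactors=config.scan.cofactors,
            window=config.scan.window, min_reps=config.cv.min_reps,
        )
        report.to_frame().to_csv(out / "null_census.csv", index=False)
        state["null_census"] = report
        record("null_census", nc.model_dump(), t0, [out / "null_census.csv"])

    # --- summaries --------------------------------------------------------
    summary_files = summarize_run(state, out)
    manifest["stages"]["summary"] = {
        "params": {}, "seed": None, "wall_clock_s": None,
        "outputs": {f.name: _sha256(f) for f in summary_files},
    }
    manifest["finished_at"] = time.time()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _concat_to(frames, path):
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    df.to_csv(path, index=False)


def _require(state: dict, key: str, stage: str, what: str):
    if key not in state:
        raise PipelineError(stage, f"missing dependency: {what} (enable the stage "
                                   "producing it or provide its files)")


def _load_inputs(config: RunConfig, out: Path, state: dict):
    paths = {
        "gmap": config.inputs.map or out / "map.tsv",
        "geno": config.inputs.genotypes or out / "genotypes.tsv",
        "obs": config.inputs.phenotypes or out / "phenotypes.csv",
    }
    readers = {"gmap": io_mod.read_map, "geno": io_mod.read_genotypes,
               "obs": io_mod.read_phenotypes}
    for key, path in paths.items():
        p = Path(path)
        if p.exists():
            state[key] = readers[key](p)


def _hotspot_markers(gmap, geno, hotspots: pd.DataFrame) -> pd.DataFrame:
    """Signed -1/+1 marker matrix: nearest marker per hotspot + CYTOPLASM."""
    cols = {}
    signed = geno.signed()
    for _, row in hotspots.iterrows():
        marker = gmap.nearest_marker(row["chromosome"], row["cm"])
        cols[marker] = signed[marker]
    cols[mm_mod.CYTOPLASM] = geno.cytoplasm_signed()
    return pd.DataFrame(cols)


def summarize_run(state: dict, out: Path) -> list[Path]:
    """Cross-stage summary tables (QTL-count frequencies, effect-size
    distributions, heritability scatter, hotspot overlap)."""
    files: list[Path] = []
    phen_all = None
    if "cv_table" in state:
        phen_all = sorted(state["cv_table"].summary["phenotype"].unique())

    for pset in ("cv", "mean"):
        peaks = state.get(f"peaks_{pset}")
        if peaks is None or phen_all is None:
            continue
        counts = peaks.groupby("phenotype").size() if len(peaks) else pd.Series(dtype=int)
        counts = counts.reindex(phen_all, fill_value=0)
        freq = counts.value_counts().sort_index().rename_axis("n_qtl").rename("n_phenotypes")
        f = out / f"qtl_count_freq_{pset}.csv"
        freq.reset_index().to_csv(f, index=False)
        files.append(f)
        if len(peaks):
            eff = peaks[["phenotype", "chromosome", "peak_cm", "percent_effect"]]
            f = out / f"effect_sizes_{pset}.csv"
            eff.to_csv(f, index=False)
            files.append(f)

    herit = state.get("heritability")
    if herit is not None and len(herit):
        wide = herit.pivot_table(index="phenotype", columns="statistic",
                                 values=["h2_nuclear", "h2_organellar"])
        wide.columns = [f"{a}_{b}" for a, b in wide.columns]
        f = out / "heritability_scatter.csv"
        wide.reset_index().to_csv(f, index=False)
        files.append(f)

    hs_cv, hs_mean = state.get("hotspots_cv"), state.get("hotspots_mean")
    if hs_cv is not None and hs_mean is not None:
        rows = []
        for _, r in hs_cv.iterrows():
            near = hs_mean[
                (hs_mean["chromosome"] == r["chromosome"])
                & ((hs_mean["cm"] - r["cm"]).abs() <= 5.0)
            ]
            rows.append(
                {"cv_hotspot": r["name"], "chromosome": r["chromosome"], "cm": r["cm"],
                 "overlapping_mean_hotspot": near["name"].iloc[0] if len(near) else ""}
            )
        f = out / "hotspot_overlap.csv"
        pd.DataFrame(rows, columns=["cv_hotspot", "chromosome", "cm",
                                    "overlapping_mean_hotspot"]).to_csv(f, index=False)
        files.append(f)
    return files
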