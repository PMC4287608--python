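"""Synthetic reciprocal RIL populations with known genetic control of noise.

Emulates the design of a replicated metabolomics QTL study: ~316 recombinant
inbred lines (RILs) from a reciprocal cross (half the lines carry each
parent's cytoplasm), genotyped on a five-chromosome map, and phenotyped for
hundreds of traits in two experiments of randomized complete blocks with two
replicates each.  Both the line mean and the line-level stochastic standard
deviation of every trait are under explicit, recoverable genetic control
(nuclear QTL, the cytoplasm as a single organellar locus, and pairwise
epistasis), so every downstream stage of the pipeline can be validated by
parameter recovery.

Genotypes are generated marker-to-marker as a two-state Markov chain using
the Haldane map function with the RIL-by-selfing expansion: for adjacent
markers d cM apart, r = (1 - exp(-2d/100)) / 2 and the observed switch
probability between fully inbred RIL genotypes is R = 2r / (1 + 2r).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "RILGenotypes",
    "DesignSpec",
    "QTLEffect",
    "EpistaticPair",
    "TrueArchitecture",
    "SimulationError",
    "haldane_r",
    "ril_switch_probability",
    "build_default_map",
    "simulate_ril_genotypes",
    "simulate_phenotypes",
    "simulate_component_phenotype",
    "default_architecture",
]

A_CYT = "A_CYT"
B_CYT = "B_CYT"


class SimulationError(RuntimeError):
    """Raised when the generative model produces non-finite moments."""


def haldane_r(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Haldane recombination fraction for a map distance in cM."""
    return (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0)) / 2.0


def ril_switch_probability(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Genotype switch probability between selfed-RIL markers d cM apart.

    The per-meiosis recombination fraction r (Haldane) accumulates over the
    selfing generations to R = 2r / (1 + 2r) between fully inbred lines.
    """
    r = haldane_r(d_cm)
    return 2.0 * r / (1.0 + 2.0 * r)


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker positions (cM) per chromosome.

    ``table`` has columns ``chromosome``, ``marker``, ``cm``; rows are
    ordered by chromosome then position.  Marker ids are unique genome-wide.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"chromosome", "marker", "cm"}
        if not required.issubset(t.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        if t["marker"].duplicated().any():
            raise ValueError("marker ids must be unique genome-wide")
        cm = t["cm"].to_numpy(dtype=float)
        if (cm < 0).any() or not np.isfinite(cm).all():
            raise ValueError("marker positions must be finite and >= 0")
        for chrom, sub in t.groupby("chromosome", sort=False):
            if not sub["cm"].is_monotonic_increasing:
                raise ValueError(f"positions not nondecreasing on {chrom}")

    @property
    def chromosomes(self) -> list:
        return list(self.table["chromosome"].unique())

    @property
    def markers(self) -> list:
        return list(self.table["marker"])

    def positions(self, chromosome) -> np.ndarray:
        sub = self.table[self.table["chromosome"] == chromosome]
        return sub["cm"].to_numpy(dtype=float)

    def chrom_markers(self, chromosome) -> list:
        return list(self.table.loc[self.table["chromosome"] == chromosome, "marker"])

    def nearest_marker(self, chromosome, position_cm: float) -> str:
        """Genotyped marker closest to a cM position (ties -> leftmost)."""
        sub = self.table[self.table["chromosome"] == chromosome]
        if sub.empty:
            raise KeyError(f"no such chromosome: {chromosome!r}")
        dist = (sub["cm"] - position_cm).abs().to_numpy()
        return sub["marker"].iloc[int(np.argmin(dist))]


@dataclass(frozen=True)
class RILGenotypes:
    """Fully inbred biallelic genotypes plus a per-line cytoplasm label.

    ``alleles`` is a line x marker DataFrame of codes "A"/"B" (A = first
    parent); ``cytoplasm`` is a line-indexed Series in {A_CYT, B_CYT}.
    """

    alleles: pd.DataFrame
    cytoplasm: pd.Series

    def __post_init__(self) -> None:
        vals = self.alleles.to_numpy()
        ok = np.isin(vals, ["A", "B"]) | pd.isna(vals)
        if not ok.all():
            raise ValueError("allele codes must be 'A' or 'B' (NaN = missing)")
        if not self.cytoplasm.index.equals(self.alleles.index):
            raise ValueError("cytoplasm must be labelled for every line")
        if not self.cytoplasm.isin([A_CYT, B_CYT]).all():
            raise ValueError(f"cytoplasm labels must be {A_CYT} or {B_CYT}")

    @property
    def lines(self) -> list:
        return list(self.alleles.index)

    def signed(self) -> pd.DataFrame:
        """Allele codes recoded to +1 (A) / -1 (B); missing -> NaN."""
        vals = self.alleles.to_numpy(dtype=object)
        out = np.full(vals.shape, np.nan)
        out[vals == "A"] = 1.0
        out[vals == "B"] = -1.0
        return pd.DataFrame(out, index=self.alleles.index, columns=self.alleles.columns)

    def cytoplasm_signed(self) -> pd.Series:
        return self.cytoplasm.map({A_CYT: 1.0, B_CYT: -1.0})


@dataclass(frozen=True)
class DesignSpec:
    """Replicated randomized-complete-block phenotyping design.

    Every line appears once per block; ``reps_per_experiment`` blocks per
    experiment.  A fixed seed makes simulator output bit-reproducible.
    """

    n_lines: int = 316
    n_experiments: int = 2
    reps_per_experiment: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 1 or self.n_experiments < 1 or self.reps_per_experiment < 1:
            raise ValueError("design counts must be positive")

    @property
    def experiments(self) -> list[str]:
        return [f"exp{i + 1}" for i in range(self.n_experiments)]

    def blocks(self, experiment: str) -> list[str]:
        return [f"{experiment}_block{j + 1}" for j in range(self.reps_per_experiment)]


@dataclass(frozen=True)
class QTLEffect:
    """A single-locus effect on either the line mean or log line SD.

    ``traits`` restricts the effect to those trait ids; None = all traits.
    """

    chromosome: object
    position_cm: float
    effect: float
    traits: tuple | None = None


@dataclass(frozen=True)
class EpistaticPair:
    """Interaction effect between two loci; "CYTOPLASM" may name a locus."""

    locus1: tuple  # (chromosome, cm) or ("CYTOPLASM", 0)
    locus2: tuple
    effect: float
    traits: tuple | None = None


@dataclass(frozen=True)
class TrueArchitecture:
    """Ground-truth genetic control of line means and line-level SDs.

    Line mean:    mu_lt = grand_mean + sum a*x + cyto_mean*z + interactions
    Line log SD:  log sigma_lt = log(base_sd) + sum b*x + cyto_sd*z
    with x, z in {-1, +1} (allele / cytoplasm coding), so an additive effect
    equals half the difference between genotype-class means.
    """

    traits: tuple
    grand_mean: float = 10.0
    base_sd: float = 1.0
    mean_qtl: tuple = ()
    var_qtl: tuple = ()
    cyto_mean_effect: dict = field(default_factory=dict)  # trait -> effect
    cyto_sd_effect: dict = field(default_factory=dict)
    epistatic_pairs: tuple = ()
    experiment_effects: dict = field(default_factory=dict)  # experiment -> shift
    block_effects: dict = field(default_factory=dict)  # block -> shift
    distribution: str = "normal"  # or "lognormal"

    def __post_init__(self) -> None:
        if not self.base_sd > 0:
            raise ValueError("base_sd must be > 0")
        effs = (
            [q.effect for q in self.mean_qtl]
            + [q.effect for q in self.var_qtl]
            + list(self.cyto_mean_effect.values())
            + list(self.cyto_sd_effect.values())
            + [p.effect for p in self.epistatic_pairs]
        )
        if effs and not np.all(np.isfinite(effs)):
            raise ValueError("all architecture effects must be finite")
        if self.distribution not in ("normal", "lognormal"):
            raise ValueError("distribution must be 'normal' or 'lognormal'")


# ---------------------------------------------------------------------------
# map and genotype generation
# ---------------------------------------------------------------------------

def build_default_map(
    n_chromosomes: int = 5,
    chrom_length: float = 90.0,
    marker_spacing: float = 5.0,
) -> GeneticMap:
    """Evenly spaced marker grid; the chromosome endpoint is always included.

    Roman-numeral chromosome ids (I..V for the default five) follow the
    Arabidopsis convention used in hotspot names.
    """
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    if marker_spacing <= 0 or chrom_length <= 0:
        raise ValueError("marker spacing and chromosome length must be > 0")
    if chrom_length < marker_spacing:
        raise ValueError("chromosome length must be >= marker spacing")
    rows = []
    for c in range(n_chromosomes):
        chrom = _roman(c + 1)
        pos = list(np.arange(0.0, chrom_length, marker_spacing))
        if not math.isclose(pos[-1], chrom_length):
            pos.append(chrom_length)
        for i, p in enumerate(pos):
            rows.append((chrom, f"m{chrom}_{i + 1:02d}", float(p)))
    return GeneticMap(pd.DataFrame(rows, columns=["chromosome", "marker", "cm"]))


def _roman(n: int) -> str:
    numerals = [
        (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
        (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
        (5, "V"), (4, "IV"), (1, "I"),
    ]
    out = []
    for value, sym in numerals:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


def simulate_ril_genotypes(gmap: GeneticMap, design: DesignSpec) -> RILGenotypes:
    """Simulate fully inbred RIL genotypes along the map.

    Each chromosome is an independent two-state Markov chain per line: the
    first marker is a fair coin, and each subsequent marker switches parent
    with probability R(d) for the inter-marker distance d (Haldane map
    function with RIL-by-selfing expansion).  Cytoplasm is assigned A_CYT to
    the first ceil(n/2) lines and B_CYT to the rest, then the line order is
    shuffled under the seed.
    """
    if gmap.table.empty:
        raise ValueError("genetic map is empty")
    rng = np.random.default_rng(design.seed)
    n = design.n_lines
    cols: list[np.ndarray] = []
    names: list[str] = []
    for chrom in gmap.chromosomes:
        pos = gmap.positions(chrom)
        state = rng.random(n) < 0.5  # True = allele A
        cols.append(state.copy())
        for j in range(1, len(pos)):
            R = ril_switch_probability(pos[j] - pos[j - 1])
            flip = rng.random(n) < R
            state = state ^ flip
            cols.append(state.copy())
        names.extend(gmap.chrom_markers(chrom))
    mat = np.where(np.column_stack(cols), "A", "B")
    lines = [f"RIL{i + 1:04d}" for i in range(n)]
    cyto = np.array([A_CYT] * math.ceil(n / 2) + [B_CYT] * (n - math.ceil(n / 2)))
    order = rng.permutation(n)
    alleles = pd.DataFrame(mat[order], index=[lines[i] for i in order], columns=names)
    cytoplasm = pd.Series(cyto[order], index=alleles.index, name="cytoplasm")
    return RILGenotypes(alleles=alleles, cytoplasm=cytoplasm)


# ---------------------------------------------------------------------------
# phenotype generation
# ---------------------------------------------------------------------------

def _locus_column(geno: RILGenotypes, gmap: GeneticMap, chromosome, cm: float) -> np.ndarray:
    if chromosome == "CYTOPLASM":
        return geno.cytoplasm_signed().to_numpy(dtype=float)
    marker = gmap.nearest_marker(chromosome, cm)
    pos = gmap.table.set_index("marker").loc[marker, "cm"]
    if abs(pos - cm) > 1e-9:
        raise ValueError(
            f"architecture locus ({chromosome}, {cm} cM) is not a genotyped marker"
        )
    return geno.signed()[marker].to_numpy(dtype=float)


def simulate_phenotypes(
    geno: RILGenotypes,
    arch: TrueArchitecture,
    design: DesignSpec,
    gmap: GeneticMap,
) -> pd.DataFrame:
    """Draw replicated observations from the generative model.

    Returns a long-format DataFrame (line, experiment, block, phenotype,
    value): every line is observed once per block per experiment, with
    observation = mu_lt + experiment shift + block shift + sigma_lt * eps,
    eps ~ N(0, 1).  With ``distribution='lognormal'`` the observation is the
    exponential of that draw (multiplicative noise).
    """
    rng = np.random.default_rng(design.seed + 1)
    lines = geno.lines
    n = len(lines)
    traits = list(arch.traits)
    t_index = {t: i for i, t in enumerate(traits)}

    mu = np.full((n, len(traits)), float(arch.grand_mean))
    log_sd = np.full((n, len(traits)), math.log(arch.base_sd))

    def _cols(trait_sel):
        if trait_sel is None:
            return slice(None)
        return [t_index[t] for t in trait_sel]

    for q in arch.mean_qtl:
        x = _locus_column(geno, gmap, q.chromosome, q.position_cm)
        mu[:, _cols(q.traits)] += q.effect * x[:, None]
    for q in arch.var_qtl:
        x = _locus_column(geno, gmap, q.chromosome, q.position_cm)
        log_sd[:, _cols(q.traits)] += q.effect * x[:, None]
    z = geno.cytoplasm_signed().to_numpy(dtype=float)
    for trait, eff in arch.cyto_mean_effect.items():
        mu[:, t_index[trait]] += eff * z
    for trait, eff in arch.cyto_sd_effect.items():
        log_sd[:, t_index[trait]] += eff * z
    for pair in arch.epistatic_pairs:
        x1 = _locus_column(geno, gmap, *pair.locus1)
        x2 = _locus_column(geno, gmap, *pair.locus2)
        mu[:, _cols(pair.traits)] += pair.effect * (x1 * x2)[:, None]

    bad = np.abs(log_sd) > 50
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise SimulationError(
            f"log SD overflow for line {lines[i]!r}, trait {traits[j]!r}"
        )
    sd = np.exp(log_sd)

    frames = []
    for exp in design.experiments:
        e_shift = float(arch.experiment_effects.get(exp, 0.0))
        for block in design.blocks(exp):
            b_shift = float(arch.block_effects.get(block, 0.0))
            eps = rng.standard_normal(mu.shape)
            vals = mu + e_shift + b_shift + sd * eps
            if arch.distribution == "lognormal":
                vals = np.exp(vals)
            frames.append(
                pd.DataFrame(
                    {
                        "line": np.repeat(lines, len(traits)),
                        "experiment": exp,
                        "block": block,
                        "phenotype": np.tile(traits, n),
                        "value": vals.ravel(),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def simulate_component_phenotype(
    cytoplasm: pd.Series,
    n_experiments: int = 2,
    var_cyto: float = 0.0,
    var_line: float = 1.0,
    var_experiment: float = 0.0,
    var_residual: float = 1.0,
    grand_mean: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw one observation per line x experiment from the components model
    y = mu + C + G(C) + E + eps, for heritability parameter-recovery checks.

    Returns a long DataFrame (line, experiment, value).
    """
    rng = np.random.default_rng(seed)
    lines = list(cytoplasm.index)
    classes = sorted(cytoplasm.unique())
    c_eff = {c: rng.normal(0.0, math.sqrt(var_cyto)) for c in classes}
    g_eff = rng.normal(0.0, math.sqrt(var_line), size=len(lines))
    rows = []
    for e in range(n_experiments):
        exp = f"exp{e + 1}"
        e_eff = rng.normal(0.0, math.sqrt(var_experiment))
        eps = rng.normal(0.0, math.sqrt(var_residual), size=len(lines))
        for i, line in enumerate(lines):
            rows.append(
                (line, exp, grand_mean + c_eff[cytoplasm[line]] + g_eff[i] + e_eff + eps[i])
            )
    return pd.DataFrame(rows, columns=["line", "experiment", "value"])


def default_architecture(
    gmap: GeneticMap,
    n_metabolites: int = 559,
    n_defense: int = 19,
    n_growth: int = 5,
    seed: int = 0,
    grand_mean: float = 10.0,
    base_sd: float = 1.0,
    mean_effect: float = 0.8,
    sd_effect: float = math.log(1.5),
    cyto_sd_effect: float = 0.15,
    n_hotspot_loci: int = 8,
) -> TrueArchitecture:
    """A study-scale architecture: hotspot loci shared across many traits.

    Traits are named ``met_*``, ``gsl_*``, ``growth_*``.  Each metabolite
    draws 0-3 mean-QTL and 0-2 variance-QTL from a fixed panel of hotspot
    loci; defense traits get larger variance effects (their noise QTL have
    roughly twice the percent effect of primary-metabolite noise QTL) and a
    subset of traits carries cytoplasm effects and cytoplasm x nuclear
    epistasis.  Effect signs are random; magnitudes are fixed at the stated
    defaults so percent effects land in the 10-25% range typical of
    metabolite QTL.
    """
    rng = np.random.default_rng(seed)
    traits = (
        [f"met_{i + 1:03d}" for i in range(n_metabolites)]
        + [f"gsl_{i + 1:02d}" for i in range(n_defense)]
        + [f"growth_{i + 1}" for i in range(n_growth)]
    )
    marker_rows = gmap.table.sample(n=min(n_hotspot_loci, len(gmap.table)),
                                    random_state=int(rng.integers(2**31 - 1)))
    loci = [(r.chromosome, float(r.cm)) for r in marker_rows.itertuples()]

    mean_qtl: dict[tuple, list] = {}
    var_qtl: dict[tuple, list] = {}
    cyto_mean: dict = {}
    cyto_sd: dict = {}
    epi: dict[tuple, list] = {}
    for t in traits:
        scale = 2.0 if t.startswith("gsl_") else 1.0
        k_mean = rng.integers(0, 4)
        k_var = rng.integers(0, 3)
        for idx in rng.choice(len(loci), size=k_mean, replace=False):
            sign = rng.choice([-1.0, 1.0])
            mean_qtl.setdefault(loci[idx], []).append((t, sign * mean_effect * scale))
        for idx in rng.choice(len(loci), size=k_var, replace=False):
            sign = rng.choice([-1.0, 1.0])
            var_qtl.setdefault(loci[idx], []).append((t, sign * sd_effect * scale))
        if rng.random() < 0.7:  # widespread organellar effect on noise
            cyto_sd[t] = rng.choice([-1.0, 1.0]) * cyto_sd_effect * scale
        if rng.random() < 0.3:
            cyto_mean[t] = rng.choice([-1.0, 1.0]) * 0.4
        if rng.random() < 0.2:
            idx = int(rng.integers(len(loci)))
            epi.setdefault((("CYTOPLASM", 0), loci[idx]), []).append(
                (t, rng.choice([-1.0, 1.0]) * 0.3)
            )

    def _group(d):
        out = []
        for locus, pairs in d.items():
            by_eff: dict[float, list] = {}
            for t, eff in pairs:
                by_eff.setdefault(eff, []).append(t)
            for eff, ts in by_eff.items():
                out.append((locus, eff, tuple(ts)))
        return out

    mean_list = tuple(
        QTLEffect(ch, cm, eff, ts) for (ch, cm), eff, ts in _group(mean_qtl)
    )
    var_list = tuple(
        QTLEffect(ch, cm, eff, ts) for (ch, cm), eff, ts in _group(var_qtl)
    )
    epi_list = tuple(
        EpistaticPair(l1, l2, eff, ts) for (l1, l2), eff, ts in _group(epi)
    )
    return TrueArchitecture(
        traits=tuple(traits),
        grand_mean=grand_mean,
        base_sd=base_sd,
        mean_qtl=mean_list,
        var_qtl=var_list,
        cyto_mean_effect=cyto_mean,
        cyto_sd_effect=cyto_sd,
        epistatic_pairs=epi_list,
        experiment_effects={"exp1": 0.0, "exp2": 0.2},
    )
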