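"""Composite interval mapping (CIM) of line-level phenotypes in RILs.

The scan regresses a line-level phenotype (mean or CV) on the conditional
probability of the first-parent allele at a grid of genome positions
(Haley-Knott regression), with background marker cofactors chosen by
forward regression; cofactors within a window of the test position are
dropped from the model (composite interval mapping).  Evidence at each
position is the LOD score

    LOD = (n/2) * log10(RSS_reduced / RSS_full)

where the full model adds the test position's genotype regressor to the
reduced (intercept + retained cofactors) model.  Significance thresholds
come from permuting the phenotype across lines (genome-wide maximum LOD
null distribution), and peaks are called with one-LOD support intervals
and additive / percent effects.

For fully inbred RILs with near-complete genotypes, Haley-Knott regression
is essentially exact, and at a genotyped marker with no cofactors the scan
reduces to single-marker regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GeneticMap, RILGenotypes, ril_switch_probability

__all__ = [
    "GenotypeProbabilityGrid",
    "ScanResult",
    "QTLPeak",
    "genotype_probabilities",
    "select_cofactors",
    "cim_scan",
    "permutation_threshold",
    "find_peaks",
    "percent_effect",
]

LOD_CAP = 300.0  # applied when the full-model RSS degenerates to ~0


@dataclass(frozen=True)
class GenotypeProbabilityGrid:
    """Conditional P(first-parent allele) on a cM grid covering the map.

    ``positions``: DataFrame (chromosome, cm, marker) where ``marker`` is
    the marker id at genotyped positions and None between markers.
    ``probs``: line x position matrix of P(A) in [0, 1]; at a genotyped,
    non-missing marker the probability is exactly 0 or 1.
    """

    positions: pd.DataFrame
    probs: np.ndarray
    lines: tuple
    gmap: GeneticMap

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def signed(self) -> np.ndarray:
        """Probabilities recoded to the [-1, +1] expected-genotype scale."""
        return 2.0 * self.probs - 1.0

    def marker_columns(self) -> pd.DataFrame:
        """Subset of positions that are genotyped markers."""
        return self.positions[self.positions["marker"].notna()]


@dataclass(frozen=True)
class ScanResult:
    """Per-position LOD and additive-effect curves from one scan.

    ``table`` columns: chromosome, cm, lod, effect, capped.  ``cofactors``
    are the marker ids available to the model (position-wise window
    exclusion happens inside the scan).
    """

    table: pd.DataFrame
    cofactors: tuple = ()

    def max_lod(self) -> float:
        return float(self.table["lod"].max()) if len(self.table) else 0.0


@dataclass(frozen=True)
class QTLPeak:
    chromosome: object
    peak_cm: float
    lod: float
    interval: tuple  # (low cM, high cM), one-LOD support
    additive_effect: float
    percent_effect: float | None = None

    def __post_init__(self) -> None:
        low, high = self.interval
        if not (low <= self.peak_cm <= high):
            raise ValueError("support interval must contain the peak")


# ---------------------------------------------------------------------------
# conditional genotype probabilities
# ---------------------------------------------------------------------------

def _chrom_grid(positions: np.ndarray, step: float) -> np.ndarray:
    lo, hi = positions[0], positions[-1]
    grid = np.arange(lo, hi, step)
    return np.unique(np.round(np.concatenate([grid, positions, [hi]]), 9))


def genotype_probabilities(
    gmap: GeneticMap, geno: RILGenotypes, step: float = 1.0
) -> GenotypeProbabilityGrid:
    """P(A allele) at every grid position, conditional on flanking markers.

    The RIL genotype process is treated as Markov along each chromosome with
    two-point switch probabilities R(d) = 2r/(1+2r), r Haldane.  Between two
    informative flanks the four flank-state path probabilities are combined;
    beyond terminal markers (or with only one informative flank) the single
    flank is used.  Missing genotypes are skipped to the nearest non-missing
    flank; a fully missing line gets probability 0.5 everywhere.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    signed = geno.signed()
    n = len(geno.lines)
    pos_rows = []
    prob_cols: list[np.ndarray] = []
    for chrom in gmap.chromosomes:
        mpos = gmap.positions(chrom)
        mnames = gmap.chrom_markers(chrom)
        # line x marker states: 1 (A), 0 (B), nan (missing)
        states = (signed[mnames].to_numpy() + 1.0) / 2.0
        grid = _chrom_grid(mpos, step)
        for q in grid:
            marker_here = None
            for name, p in zip(mnames, mpos):
                if abs(p - q) < 1e-9:
                    marker_here = name
                    break
            pos_rows.append((chrom, float(q), marker_here))
            prob_cols.append(_prob_at(q, mpos, states))
    positions = pd.DataFrame(pos_rows, columns=["chromosome", "cm", "marker"])
    probs = np.column_stack(prob_cols)
    return GenotypeProbabilityGrid(
        positions=positions, probs=probs, lines=tuple(geno.lines), gmap=gmap
    )


def _prob_at(q: float, mpos: np.ndarray, states: np.ndarray) -> np.ndarray:
    """P(A at q) per line given observed marker states on one chromosome."""
    n = states.shape[0]
    if not np.isnan(states).any():
        # complete-data fast path: common flanks for every line
        left = np.where(mpos <= q + 1e-9)[0]
        right = np.where(mpos >= q - 1e-9)[0]
        L = left[-1] if left.size else None
        Rr = right[0] if right.size else None
        if L is not None and Rr is not None and L == Rr:
            return states[:, L].astype(float)
        if L is None or Rr is None:
            j = L if Rr is None else Rr
            R = ril_switch_probability(abs(q - mpos[j]))
            return np.where(states[:, j] == 1, 1 - R, R)
        RL = ril_switch_probability(q - mpos[L])
        RR = ril_switch_probability(mpos[Rr] - q)
        tL = np.where(states[:, L] == 1, 1 - RL, RL)  # P(left state -> A)
        tR = np.where(states[:, Rr] == 1, 1 - RR, RR)  # P(A -> right state)
        pA = tL * tR
        pB = (1 - tL) * (1 - tR)
        return pA / (pA + pB)
    out = np.full(n, 0.5)
    observed = ~np.isnan(states)
    left_idx = np.where(mpos <= q + 1e-9)[0]
    right_idx = np.where(mpos >= q - 1e-9)[0]
    for i in range(n):
        obs_cols = np.where(observed[i])[0]
        if obs_cols.size == 0:
            continue
        li = [j for j in left_idx if observed[i, j]]
        ri = [j for j in right_idx if observed[i, j]]
        L = li[-1] if li else None
        Rr = ri[0] if ri else None
        if L is not None and Rr is not None and L == Rr:
            out[i] = states[i, L]
        elif L is not None and Rr is not None:
            RL = ril_switch_probability(q - mpos[L])
            RR = ril_switch_probability(mpos[Rr] - q)
            sL, sR = states[i, L], states[i, Rr]
            pA = (RL if sL == 0 else 1 - RL) * (RR if sR == 0 else 1 - RR)
            pB = ((1 - RL) if sL == 0 else RL) * ((1 - RR) if sR == 0 else RR)
            out[i] = pA / (pA + pB)
        elif L is not None:
            R = ril_switch_probability(q - mpos[L])
            out[i] = 1 - R if states[i, L] == 1 else R
        else:
            R = ril_switch_probability(mpos[Rr] - q)
            out[i] = 1 - R if states[i, Rr] == 1 else R
    return out


# ---------------------------------------------------------------------------
# regression machinery (shared by selection, scan, permutations)
# ---------------------------------------------------------------------------

def _residualize(Q: np.ndarray | None, M: np.ndarray) -> np.ndarray:
    """Residual of columns of M after projecting out an orthonormal basis Q."""
    if Q is None:
        return M - M.mean(axis=0, keepdims=True)
    return M - Q @ (Q.T @ M)


def _orthonormal_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of X (rank-revealing)."""
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    return q[:, keep]


def select_cofactors(
    grid: GenotypeProbabilityGrid,
    phenotype: pd.Series | np.ndarray,
    k: int = 3,
) -> list:
    """Greedy forward selection of ``k`` marker cofactors.

    At each step the genotyped marker giving the largest reduction in
    residual sum of squares of the linear fit (intercept + chosen markers)
    is added; ties break by map order, and candidates made (near-)collinear
    with the current model are skipped.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    y = np.asarray(phenotype, dtype=float)
    markers = grid.marker_columns()
    if k > len(markers):
        raise ValueError("fewer markers than requested cofactors")
    if k == 0:
        return []
    X = grid.signed()[:, markers.index.to_numpy()]
    names = markers["marker"].tolist()
    n = len(y)
    chosen: list[int] = []
    basis = np.ones((n, 1)) / np.sqrt(n)
    ey = _residualize(basis, y[:, None])[:, 0]
    E = _residualize(basis, X)
    for _ in range(k):
        denom = np.einsum("ij,ij->j", E, E)
        numer = (E.T @ ey) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            gain = np.where(denom > 1e-10 * n, numer / denom, -np.inf)
        gain[chosen] = -np.inf
        best = int(np.argmax(gain))  # argmax takes the first (map-order) tie
        if not np.isfinite(gain[best]):
            break
        chosen.append(best)
        u = E[:, best] / np.linalg.norm(E[:, best])
        ey = ey - u * (u @ ey)
        E = E - np.outer(u, u @ E)
    return [names[i] for i in chosen]


def _scan_arrays(
    grid: GenotypeProbabilityGrid,
    y: np.ndarray,
    cofactor_idx: np.ndarray,
    window: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised CIM scan; returns (lod, effect, capped) per grid position.

    Positions are grouped by their retained-cofactor subset (cofactors
    within ``window`` cM on the same chromosome are dropped), so each group
    needs one orthonormal basis and a couple of matrix products.
    """
    n = len(y)
    pos = grid.positions
    X = grid.signed()
    chrom = pos["chromosome"].to_numpy()
    cm = pos["cm"].to_numpy(dtype=float)

    cof_chrom = chrom[cofactor_idx] if len(cofactor_idx) else np.array([], dtype=object)
    cof_cm = cm[cofactor_idx] if len(cofactor_idx) else np.array([])
    m = grid.n_positions
    if len(cofactor_idx):
        same = chrom[:, None] == cof_chrom[None, :]
        near = np.abs(cm[:, None] - cof_cm[None, :]) <= window
        keep_mask = ~(same & near)  # position x cofactor retained flags
    else:
        keep_mask = np.ones((m, 0), dtype=bool)

    lod = np.zeros(m)
    eff = np.zeros(m)
    capped = np.zeros(m, dtype=bool)
    ss_tot_basis = np.ones((n, 1)) / np.sqrt(n)

    keys = [tuple(np.nonzero(row)[0]) for row in keep_mask]
    for key in set(keys):
        sel = np.array([k == key for k in keys])
        kept = cofactor_idx[list(key)] if key else np.array([], dtype=int)
        design = [np.ones((n, 1))]
        if len(kept):
            design.append(X[:, kept])
        Q = _orthonormal_basis(np.hstack(design))
        ey = y - Q @ (Q.T @ y)
        rss_red = float(ey @ ey)
        E = X[:, sel] - Q @ (Q.T @ X[:, sel])
        denom = np.einsum("ij,ij->j", E, E)
        numer_b = E.T @ ey
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(denom > 1e-12 * n, numer_b / denom, 0.0)
            rss_full = rss_red - np.where(denom > 1e-12 * n, numer_b**2 / denom, 0.0)
        tiny = rss_full <= 1e-12 * rss_red
        with np.errstate(divide="ignore"):
            l = (n / 2.0) * np.log10(np.where(tiny, 1.0, rss_red / rss_full))
        l[tiny] = LOD_CAP
        lod[sel] = np.maximum(l, 0.0)
        eff[sel] = beta  # beta on the +/-1 scale = half the class-mean difference
        capped[sel] = tiny
    return lod, eff, capped


def cim_scan(
    grid: GenotypeProbabilityGrid,
    phenotype: pd.Series | np.ndarray,
    cofactors: list | tuple = (),
    window: float = 10.0,
) -> ScanResult:
    """Haley-Knott composite interval mapping scan of one phenotype.

    ``phenotype`` is a line-level value aligned with ``grid.lines`` (a
    Series is reindexed by line id).  ``cofactors`` are marker ids; at each
    position those within ``window`` cM on the same chromosome are dropped
    from the model.  NaN phenotypes drop the line from the scan.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    y, rows = _align_phenotype(grid, phenotype)
    if len(y) < 10:
        raise ValueError("phenotype defined for fewer than 10 lines")
    sub = grid if rows is None else _subset_lines(grid, rows)
    cof_idx = _cofactor_indices(grid, cofactors)
    lod, eff, capped = _scan_arrays(sub, y, cof_idx, window)
    table = grid.positions[["chromosome", "cm"]].copy()
    table["lod"] = lod
    table["effect"] = eff
    table["capped"] = capped
    return ScanResult(table=table, cofactors=tuple(cofactors))


def _align_phenotype(grid, phenotype):
    if isinstance(phenotype, pd.Series):
        y = phenotype.reindex(list(grid.lines)).to_numpy(dtype=float)
    else:
        y = np.asarray(phenotype, dtype=float)
        if len(y) != len(grid.lines):
            raise ValueError("phenotype length does not match grid lines")
    ok = np.isfinite(y)
    if ok.all():
        return y, None
    return y[ok], np.where(ok)[0]


def _subset_lines(grid: GenotypeProbabilityGrid, rows: np.ndarray) -> GenotypeProbabilityGrid:
    return GenotypeProbabilityGrid(
        positions=grid.positions,
        probs=grid.probs[rows],
        lines=tuple(np.asarray(grid.lines, dtype=object)[rows]),
        gmap=grid.gmap,
    )


def _cofactor_indices(grid: GenotypeProbabilityGrid, cofactors) -> np.ndarray:
    try:
        return np.array(
            [int(grid.positions.index[grid.positions["marker"] == c][0]) for c in cofactors],
            dtype=int,
        )
    except IndexError as exc:
        raise KeyError(f"cofactor not on the grid: {list(cofactors)}") from exc


def permutation_threshold(
    grid: GenotypeProbabilityGrid,
    phenotype: pd.Series | np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    reselect_cofactors: bool = True,
    seed: int = 0,
    k_cofactors: int = 3,
    window: float = 10.0,
    cofactors: list | tuple = (),
) -> float:
    """Genome-wide LOD threshold from phenotype permutations.

    The phenotype is permuted across lines; each permutation is rescanned
    (with cofactors reselected by forward regression when
    ``reselect_cofactors`` is set, else the supplied frozen ``cofactors``)
    and the genome-wide maximum LOD recorded.  The threshold is the
    empirical (1 - alpha) quantile, taken as the ceil((1-alpha)*n_perm)-th
    order statistic (type-1 empirical quantile).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    y, rows = _align_phenotype(grid, phenotype)
    if np.allclose(y, y[0]):
        raise ValueError("constant phenotype: permutation null is degenerate")
    sub = grid if rows is None else _subset_lines(grid, rows)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    frozen_idx = _cofactor_indices(grid, cofactors) if not reselect_cofactors else None
    for p in range(n_perm):
        yp = rng.permutation(y)
        if reselect_cofactors:
            cofs = select_cofactors(sub, yp, k_cofactors)
            idx = _cofactor_indices(grid, cofs)
        else:
            idx = frozen_idx
        lod, _, _ = _scan_arrays(sub, yp, idx, window)
        maxima[p] = lod.max()
    order = int(np.ceil((1 - alpha) * n_perm)) - 1
    return float(np.sort(maxima)[order])


# ---------------------------------------------------------------------------
# peak calling
# ---------------------------------------------------------------------------

def find_peaks(
    scan: ScanResult,
    lod_min: float = 2.0,
    trait_mean: float | None = None,
) -> list[QTLPeak]:
    """Call QTL peaks with one-LOD support intervals.

    Local maxima with LOD >= ``lod_min``; two maxima on one chromosome are
    distinct peaks only if the curve between them dips at least 1 LOD below
    the smaller of the two.  The support interval is the widest contiguous
    run around the peak with LOD >= peak - 1, clipped to the chromosome.
    Supplying ``trait_mean`` attaches percent effects.
    """
    if lod_min <= 0:
        raise ValueError("lod_min must be > 0")
    peaks: list[QTLPeak] = []
    for chrom, sub in scan.table.groupby("chromosome", sort=False):
        cm = sub["cm"].to_numpy(dtype=float)
        lod = sub["lod"].to_numpy(dtype=float)
        eff = sub["effect"].to_numpy(dtype=float)
        cand = [
            i for i in range(len(lod))
            if lod[i] >= lod_min
            and (i == 0 or lod[i] >= lod[i - 1])
            and (i == len(lod) - 1 or lod[i] >= lod[i + 1])
        ]
        accepted: list[int] = []
        for i in sorted(cand, key=lambda j: (-lod[j], cm[j])):
            distinct = True
            for j in accepted:
                lo, hi = sorted((i, j))
                valley = lod[lo : hi + 1].min()
                if valley > min(lod[i], lod[j]) - 1.0:
                    distinct = False
                    break
            if distinct:
                accepted.append(i)
        for i in sorted(accepted, key=lambda j: cm[j]):
            thr = lod[i] - 1.0
            lo = i
            while lo > 0 and lod[lo - 1] >= thr:
                lo -= 1
            hi = i
            while hi < len(lod) - 1 and lod[hi + 1] >= thr:
                hi += 1
            pct = None
            if trait_mean is not None:
                pct = percent_effect(eff[i], trait_mean)
            peaks.append(
                QTLPeak(
                    chromosome=chrom,
                    peak_cm=float(cm[i]),
                    lod=float(lod[i]),
                    interval=(float(cm[lo]), float(cm[hi])),
                    additive_effect=float(eff[i]),
                    percent_effect=pct,
                )
            )
    return peaks


def percent_effect(a: float, trait_mean_over_lines: float) -> float:
    """Allelic-substitution effect as a percentage of the trait mean.

    100 * |2a| / |mean|: the full difference between genotype-class means
    (twice the additive effect) relative to the population mean.
    """
    if trait_mean_over_lines == 0:
        raise ZeroDivisionError("percent effect undefined for zero trait mean")
    return 100.0 * abs(2.0 * a) / abs(trait_mean_over_lines)


def peaks_to_table(peaks_by_phenotype: dict) -> pd.DataFrame:
    """Flatten {phenotype: [QTLPeak, ...]} into a peak table."""
    rows = []
    for phen, peaks in peaks_by_phenotype.items():
        for p in peaks:
            rows.append(
                {
                    "phenotype": phen,
                    "chromosome": p.chromosome,
                    "peak_cm": p.peak_cm,
                    "lod": p.lod,
                    "interval_low": p.interval[0],
                    "interval_high": p.interval[1],
                    "additive_effect": p.additive_effect,
                    "percent_effect": p.percent_effect,
                }
            )
    cols = ["phenotype", "chromosome", "peak_cm", "lod", "interval_low",
            "interval_high", "additive_effect", "percent_effect"]
    return pd.DataFrame(rows, columns=cols)
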