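"""QTL hotspot detection by sliding-window peak summation.

Peaks from many phenotypes are summed in a sliding window along the map
(each phenotype contributes 1 at each of its peak positions), giving a
per-window count of phenotypes mapping there.  A permutation null —
relocating every phenotype's peaks to uniform random map positions while
preserving per-phenotype peak counts — gives the genome-wide threshold for
calling a window a hotspot.  Hotspots are named PREFIX.CHROM.cM, e.g.
``M.CV.II.16`` for a metabolite-CV hotspot on chromosome II at 16 cM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GeneticMap

__all__ = ["HotspotProfile", "window_counts", "hotspot_threshold", "name_hotspots"]


@dataclass(frozen=True)
class HotspotProfile:
    """Window counts plus (optionally) a threshold and named hotspots.

    ``counts`` columns: chromosome, cm (window center), count.  Windows are
    half-open intervals [c - w/2, c + w/2) at a fixed step.
    """

    counts: pd.DataFrame
    window: float
    step: float
    threshold: float | None = None
    hotspots: pd.DataFrame | None = None


def _window_centers(gmap: GeneticMap, step: float) -> pd.DataFrame:
    rows = []
    for chrom in gmap.chromosomes:
        pos = gmap.positions(chrom)
        centers = np.arange(pos[0], pos[-1] + step / 2, step)
        for c in centers:
            rows.append((chrom, float(c)))
    return pd.DataFrame(rows, columns=["chromosome", "cm"])


def _counts_from_positions(
    centers: pd.DataFrame, peak_positions: pd.DataFrame, window: float
) -> np.ndarray:
    """Count phenotypes with >=1 peak in each window.

    ``peak_positions`` columns: phenotype, chromosome, peak_cm.  A window
    [c - w/2, c + w/2) covers a peak at x iff x - w/2 < c <= x + w/2, a
    contiguous run of window centers; multiple peaks of one phenotype in
    the same window still count once (distinct phenotypes per window).
    """
    counts = np.zeros(len(centers), dtype=int)
    if len(peak_positions) == 0:
        return counts
    half = window / 2.0
    phen_codes, _ = pd.factorize(peak_positions["phenotype"])
    n_phen = int(phen_codes.max()) + 1
    c_chrom = centers["chromosome"].to_numpy()
    c_cm = centers["cm"].to_numpy(dtype=float)
    p_chrom = peak_positions["chromosome"].to_numpy()
    p_cm = peak_positions["peak_cm"].to_numpy(dtype=float)
    for chrom in pd.unique(c_chrom):
        cidx = np.where(c_chrom == chrom)[0]
        ccm = c_cm[cidx]  # centers are generated sorted per chromosome
        sel = p_chrom == chrom
        if not sel.any():
            continue
        x = p_cm[sel]
        ph = phen_codes[sel]
        eps = 1e-9
        lo = np.searchsorted(ccm, x - half + eps, side="left")
        hi = np.searchsorted(ccm, x + half + eps, side="left")
        reps = hi - lo
        if reps.sum() == 0:
            continue
        within = np.arange(reps.sum()) - np.repeat(np.cumsum(reps) - reps, reps)
        win_idx = np.repeat(lo, reps) + within
        pairs = np.unique(win_idx.astype(np.int64) * n_phen + np.repeat(ph, reps))
        counts[cidx] += np.bincount(pairs // n_phen, minlength=len(ccm)).astype(int)
    return counts


def window_counts(
    peak_table: pd.DataFrame,
    gmap: GeneticMap,
    window: float = 5.0,
    step: float = 1.0,
) -> HotspotProfile:
    """Sliding-window counts of phenotypes with a peak in each window.

    ``peak_table`` needs columns phenotype, chromosome, peak_cm (as written
    by the scan stage).  Peaks off the map are rejected.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be > 0")
    centers = _window_centers(gmap, step)
    if len(peak_table):
        for chrom, sub in peak_table.groupby("chromosome"):
            if chrom not in gmap.chromosomes:
                raise ValueError(f"peak on unknown chromosome {chrom!r}")
            pos = gmap.positions(chrom)
            if ((sub["peak_cm"] < pos[0]) | (sub["peak_cm"] > pos[-1])).any():
                raise ValueError(f"peak off the map on chromosome {chrom!r}")
    counts = _counts_from_positions(centers, peak_table, window)
    table = centers.copy()
    table["count"] = counts
    return HotspotProfile(counts=table, window=window, step=step)


def hotspot_threshold(
    peak_table: pd.DataFrame,
    gmap: GeneticMap,
    window: float = 5.0,
    step: float = 1.0,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Permutation threshold for the genome-wide maximum window count.

    Each permutation relocates every phenotype's peaks to uniform random
    positions on the map (per-phenotype peak counts preserved, chromosome
    chosen with probability proportional to its cM length) and records the
    maximum window count; the threshold is the empirical (1 - alpha)
    quantile (type-1 order statistic) of those maxima.  A window whose
    observed count strictly exceeds the threshold is hotspot-significant.
    """
    if len(peak_table) == 0:
        raise ValueError("no peaks: hotspot threshold undefined")
    rng = np.random.default_rng(seed)
    centers = _window_centers(gmap, step)
    chroms = gmap.chromosomes
    spans = np.array([gmap.positions(c)[-1] - gmap.positions(c)[0] for c in chroms], dtype=float)
    starts = np.array([gmap.positions(c)[0] for c in chroms], dtype=float)
    probs = spans / spans.sum()
    n_peaks = len(peak_table)
    phen = peak_table["phenotype"].to_numpy()
    maxima = np.empty(n_perm)
    for p in range(n_perm):
        ci = rng.choice(len(chroms), size=n_peaks, p=probs)
        cm = starts[ci] + rng.random(n_peaks) * spans[ci]
        perm = pd.DataFrame(
            {"phenotype": phen, "chromosome": np.array(chroms, dtype=object)[ci], "peak_cm": cm}
        )
        maxima[p] = _counts_from_positions(centers, perm, window).max()
    order = int(np.ceil((1 - alpha) * n_perm)) - 1
    return float(np.sort(maxima)[order])


def name_hotspots(profile: HotspotProfile, threshold: float, prefix: str) -> HotspotProfile:
    """Merge contiguous supra-threshold windows and name each hotspot.

    Windows with count > threshold are merged when contiguous (adjacent
    centers one step apart on the same chromosome); each merged region
    emits one hotspot at its maximal-count window center (ties -> leftmost),
    named ``{prefix}.{chromosome}.{cM}`` with the cM position rounded to the
    nearest integer.
    """
    rows = []
    for chrom, sub in profile.counts.groupby("chromosome", sort=False):
        sub = sub.sort_values("cm")
        over = sub[sub["count"] > threshold]
        if over.empty:
            continue
        cms = over["cm"].to_numpy()
        cnts = over["count"].to_numpy()
        breaks = np.where(np.diff(cms) > profile.step * 1.5)[0]
        segments = np.split(np.arange(len(cms)), breaks + 1)
        for seg in segments:
            best = seg[int(np.argmax(cnts[seg]))]  # argmax -> leftmost tie
            cm = float(cms[best])
            rows.append(
                {
                    "name": f"{prefix}.{chrom}.{int(round(cm))}",
                    "chromosome": chrom,
                    "cm": cm,
                    "count": int(cnts[best]),
                }
            )
    hotspots = pd.DataFrame(rows, columns=["name", "chromosome", "cm", "count"])
    return HotspotProfile(
        counts=profile.counts,
        window=profile.window,
        step=profile.step,
        threshold=threshold,
        hotspots=hotspots,
    )
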