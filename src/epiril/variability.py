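"""Cross-strain methylation-variability classification.

Each CG's methylation levels across a strain panel are binned into five
equal bins (lo, medlo, med, medhi, hi; left-closed, right-open, last bin
closed). Local maxima of the 5-bin histogram containing at least 5% of
strains are peaks (equal-valued adjacent bins collapse to one plateau peak,
reported at its leftmost bin). The peak count and the density concentrated
in peak bins assign a category (unimodal/bimodal sharp or inter, trimodal,
distributed) and subcategory, which map onto six overall classes (invariant
low/high, bimodal low/med/high, distributed) and onto the three-class
variant (unimodal_lo, unimodal_hi, variable) used for small panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

BIN_NAMES = ["lo", "medlo", "med", "medhi", "hi"]
DEFAULT_MIN_STRAINS_FRACTION = 627 / 927  # coverage rule scaled to panel size


@dataclass
class VariabilityCall:
    category: str          # unimodal_sharp/unimodal_inter/bimodal_*/trimodal/distributed
    subcategory: str | None
    class6: str
    class3: str
    peaks: tuple


def default_min_strains(panel_size: int) -> int:
    return math.ceil(DEFAULT_MIN_STRAINS_FRACTION * panel_size)


def bin_levels(levels) -> np.ndarray:
    """Bin index (0..4) per level; bins left-closed, last bin closed."""
    levels = np.asarray(levels, dtype=float)
    return np.minimum((levels * 5).astype(int), 4)


def bin_distribution(levels, coverage=None, min_cov: int = 5,
                     min_strains: int | None = None,
                     panel_size: int | None = None):
    """Five-bin strain distribution for one site, or None if undercovered.

    Strains with coverage below ``min_cov`` are excluded; the site is
    missing when fewer than ``min_strains`` strains qualify (default:
    ceil(0.676 * panel size)).
    """
    levels = np.asarray(levels, dtype=float)
    ok = ~np.isnan(levels)
    if coverage is not None:
        ok &= np.asarray(coverage) >= min_cov
    if min_strains is None:
        min_strains = default_min_strains(
            panel_size if panel_size is not None else len(levels))
    if ok.sum() < min_strains:
        return None
    counts = np.bincount(bin_levels(levels[ok]), minlength=5)
    return counts / counts.sum()


def find_peaks(dist: np.ndarray, min_peak: float = 0.05) -> list[int]:
    """Local-maximum bins holding >= min_peak of strains.

    Runs of equal adjacent values collapse to one plateau peak reported at
    the leftmost bin of the run.
    """
    dist = np.asarray(dist, dtype=float)
    # runs of equal values
    runs = []  # (start_bin, end_bin_exclusive, value)
    start = 0
    for i in range(1, len(dist) + 1):
        if i == len(dist) or dist[i] != dist[start]:
            runs.append((start, i, dist[start]))
            start = i
    peaks = []
    for ri, (s, e, v) in enumerate(runs):
        left_ok = ri == 0 or runs[ri - 1][2] < v
        right_ok = ri == len(runs) - 1 or runs[ri + 1][2] < v
        if left_ok and right_ok and v >= min_peak:
            peaks.append(s)
    return peaks


def _peak_run_bins(dist: np.ndarray, peak: int) -> list[int]:
    bins = [peak]
    j = peak + 1
    while j < len(dist) and dist[j] == dist[peak]:
        bins.append(j)
        j += 1
    return bins


def classify_site(dist, min_peak: float = 0.05,
                  sharp_threshold: float = 0.90) -> VariabilityCall | None:
    """Category, subcategory and 6-/3-class groupings for one distribution."""
    if dist is None:
        return None
    dist = np.asarray(dist, dtype=float)
    peaks = find_peaks(dist, min_peak)
    peak_bins = sorted({b for p in peaks for b in _peak_run_bins(dist, p)})
    peak_density = dist[peak_bins].sum() if peak_bins else 0.0
    sharp = peak_density >= sharp_threshold

    if len(peaks) == 1:
        category = "unimodal_sharp" if sharp else "unimodal_inter"
        sub = BIN_NAMES[peaks[0]]
        if sub in ("lo", "medlo"):
            class6 = "invariant_low"
        elif sub in ("hi", "medhi"):
            class6 = "invariant_high"
        else:
            class6 = "distributed"
    elif len(peaks) == 2:
        category = "bimodal_sharp" if sharp else "bimodal_inter"
        h = dist[peaks]
        top = peaks[int(np.argmax(h))]   # leftmost wins ties -> "similar"
        hi_val, lo_val = float(h.max()), float(h.min())
        if hi_val > 4.0 * lo_val:
            kind = "mostly"
        elif hi_val > 1.5 * lo_val:
            kind = "biased"
        else:
            kind = "similar"
        loc = BIN_NAMES[top]
        sub = f"{kind} {loc}"
        if kind == "mostly" and loc in ("hi", "medhi"):
            class6 = "bimodal_high"
        elif kind == "mostly" and loc in ("lo", "medlo"):
            class6 = "bimodal_low"
        else:
            class6 = "bimodal_med"
    elif len(peaks) == 3:
        category, sub, class6 = "trimodal", None, "distributed"
    else:
        category, sub, class6 = "distributed", None, "distributed"

    if class6 == "invariant_low":
        class3 = "unimodal_lo"
    elif class6 == "invariant_high":
        class3 = "unimodal_hi"
    else:
        class3 = "variable"
    return VariabilityCall(category, sub, class6, class3, tuple(peaks))


def classify_panel(levels: pd.DataFrame, coverage: pd.DataFrame | None = None,
                   min_cov: int = 5, min_strains: int | None = None,
                   min_peak: float = 0.05,
                   sharp_threshold: float = 0.90) -> pd.DataFrame:
    """Classify every site of a sites-by-strains level matrix.

    Returns one row per classifiable site with category, subcategory,
    class6 and class3 columns; undercovered sites are omitted.
    """
    panel_size = levels.shape[1]
    rows = {}
    cov_arr = coverage.to_numpy() if coverage is not None else None
    lev_arr = levels.to_numpy()
    for i, site in enumerate(levels.index):
        dist = bin_distribution(
            lev_arr[i], cov_arr[i] if cov_arr is not None else None,
            min_cov=min_cov, min_strains=min_strains, panel_size=panel_size)
        call = classify_site(dist, min_peak, sharp_threshold)
        if call is None:
            continue
        rows[site] = (call.category, call.subcategory, call.class6,
                      call.class3)
    return pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["category", "subcategory", "class6", "class3"])


def classify_panel_small(levels: pd.DataFrame, max_missing_strains: int = 1,
                         min_peak: float = 0.05,
                         sharp_threshold: float = 0.90) -> pd.Series:
    """Three-class variant for small strain panels (e.g. 5-7 inbred lines).

    Sites with data missing (NaN) in more than ``max_missing_strains``
    strains are excluded; the bimodal classes merge with distributed into a
    single "variable" class.
    """
    if levels.shape[1] < 5:
        raise ValueError("panel must contain at least 5 strains")
    out = {}
    for site, row in levels.iterrows():
        vals = row.to_numpy(dtype=float)
        n_missing = int(np.isnan(vals).sum())
        if n_missing > max_missing_strains:
            continue
        vals = vals[~np.isnan(vals)]
        counts = np.bincount(bin_levels(vals), minlength=5)
        call = classify_site(counts / counts.sum(), min_peak,
                             sharp_threshold)
        out[site] = call.class3
    return pd.Series(out, name="class3", dtype=object)
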