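"""Spatial statistics for dynamic CG sites.

Physical clustering is measured by f100, the fraction of within-chromosome
nearest-neighbor distances <= 100 bp, compared against a resampling null:
random subsets of matching size drawn (without replacement) from the
background site set, N = 1000 times; the z-score of the observed f100
against the resampled mean/s.d. gives an upper-tail normal p (an empirical
permutation p is reported alongside). Positional metaplots (ends analysis),
relative-rate profiles, sequence-composition permutation tests and
small-RNA overlap scoring live here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm


@dataclass
class ClusteringResult:
    f100_observed: float
    bg_mean: float
    bg_sd: float
    z: float
    p: float                 # upper-tail normal approximation
    p_empirical: float
    n_resamples: int
    degenerate: bool = False


@dataclass
class CompositionTestResult:
    observed: float
    right_tail_count: int    # permuted means greater than observed
    left_tail_count: int
    n_perm: int
    p_right: float
    p_left: float
    significant: bool
    tail_cutoff: int


def nn_distances(sites: pd.DataFrame) -> pd.Series:
    """Distance from each site to the nearest other site on its chromosome.

    Chromosome-singleton sites yield no distance.
    """
    pieces = []
    for chrom, grp in sites.groupby("chrom", sort=False):
        pos = np.sort(grp["pos"].to_numpy())
        if len(pos) < 2:
            continue
        gaps = np.diff(pos)
        left = np.concatenate([[np.inf], gaps])
        right = np.concatenate([gaps, [np.inf]])
        pieces.append(pd.Series(np.minimum(left, right)))
    if not pieces:
        return pd.Series(dtype=float)
    return pd.concat(pieces, ignore_index=True)


def f_near(sites: pd.DataFrame, threshold: float = 100.0) -> float:
    """Fraction of nearest-neighbor distances <= threshold (f100)."""
    d = nn_distances(sites)
    return float((d <= threshold).mean()) if len(d) else float("nan")


def zscore(observed: float, bg_mean: float, bg_sd: float) -> float:
    """Standard score of an observed statistic against a resampled null."""
    return (observed - bg_mean) / bg_sd


def clustering_ztest(true_sites: pd.DataFrame,
                     background_sites: pd.DataFrame,
                     n_resamples: int = 1000, seed=0,
                     threshold: float = 100.0) -> ClusteringResult:
    """Resampling z-test for physical clustering of a site subset."""
    true_keys = set(zip(true_sites["chrom"], true_sites["pos"]))
    bg_keys = set(zip(background_sites["chrom"], background_sites["pos"]))
    if not true_keys <= bg_keys:
        raise ValueError("true sites must be a subset of the background")
    rng = np.random.default_rng(seed)
    observed = f_near(true_sites, threshold)

    chroms = background_sites["chrom"].to_numpy()
    positions = background_sites["pos"].to_numpy()
    chrom_codes, _ = pd.factorize(chroms)
    n_true = len(true_sites)
    stats = np.empty(n_resamples)
    for i in range(n_resamples):
        pick = rng.choice(len(positions), size=n_true, replace=False)
        stats[i] = _f_near_arrays(chrom_codes[pick], positions[pick],
                                  threshold)
    bg_mean = float(stats.mean())
    bg_sd = float(stats.std(ddof=1))
    degenerate = bg_sd == 0.0
    z = zscore(observed, bg_mean, bg_sd) if not degenerate else float("nan")
    p = float(norm.sf(z)) if not degenerate else float("nan")
    p_emp = float((1 + (stats >= observed).sum()) / (n_resamples + 1))
    return ClusteringResult(observed, bg_mean, bg_sd, z, p, p_emp,
                            n_resamples, degenerate)


def _f_near_arrays(chrom_codes: np.ndarray, positions: np.ndarray,
                   threshold: float) -> float:
    order = np.lexsort((positions, chrom_codes))
    cc = chrom_codes[order]
    pp = positions[order]
    gaps = np.diff(pp).astype(float)
    same = np.diff(cc) == 0
    gaps[~same] = np.inf
    left = np.concatenate([[np.inf], gaps])
    right = np.concatenate([gaps, [np.inf]])
    nn = np.minimum(left, right)
    finite = np.isfinite(nn)
    if not finite.any():
        return float("nan")
    return float((nn[finite] <= threshold).mean())


# ---------------------------------------------------------------------------
# metaplots


def ends_metaplot(track: pd.DataFrame, features: pd.DataFrame,
                  inside: int = 0, outside: int = 100,
                  width: int = 20) -> pd.DataFrame:
    """Average a positional track in bins around feature 5' and 3' ends.

    ``track`` has columns chrom, pos, value (values defined only at
    covered positions, e.g. cytosines); ``features`` is BED-like with
    strand. Bins tile [-outside, +inside) around the 5' end and
    [-inside, +outside) around the 3' end in feature-oriented coordinates
    (minus-strand features are mirrored). Inside bins whose span crosses
    the feature midpoint are dropped for that feature. Returns the mean
    per bin over per-feature bin means.
    """
    edges5 = np.arange(-outside, inside + 1, width)
    edges3 = np.arange(-inside, outside + 1, width)
    sums = {"5p": np.zeros(len(edges5) - 1), "3p": np.zeros(len(edges3) - 1)}
    counts = {"5p": np.zeros(len(edges5) - 1), "3p": np.zeros(len(edges3) - 1)}

    by_chrom = {c: g.sort_values("pos") for c, g in track.groupby("chrom")}
    for feat in features.itertuples():
        sub = by_chrom.get(feat.chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        val = sub["value"].to_numpy()
        length = feat.end - feat.start
        strand = getattr(feat, "strand", "+")
        if strand == "-":
            # 5' end at end-1, transcription toward lower coordinates
            rel5 = (feat.end - 1) - pos
            rel3 = feat.start - pos
        else:
            rel5 = pos - feat.start
            rel3 = pos - (feat.end - 1)
        for side, rel, edges in (("5p", rel5, edges5), ("3p", rel3, edges3)):
            idx = np.searchsorted(edges, rel, side="right") - 1
            ok = (idx >= 0) & (idx < len(edges) - 1)
            # drop inside bins crossing the feature midpoint
            if side == "5p":
                inside_rel = rel
            else:
                inside_rel = -rel
            ok &= ~((inside_rel >= 0) & (inside_rel > length / 2))
            if not ok.any():
                continue
            bin_sum = np.bincount(idx[ok], weights=val[ok],
                                  minlength=len(edges) - 1)
            bin_n = np.bincount(idx[ok], minlength=len(edges) - 1)
            with np.errstate(invalid="ignore"):
                mean = np.where(bin_n > 0, bin_sum / np.maximum(bin_n, 1),
                                np.nan)
            has = bin_n > 0
            sums[side][has] += mean[has]
            counts[side][has] += 1

    frames = []
    for side, edges in (("5p", edges5), ("3p", edges3)):
        with np.errstate(invalid="ignore"):
            value = np.where(counts[side] > 0,
                             sums[side] / np.maximum(counts[side], 1), np.nan)
        frames.append(pd.DataFrame({
            "side": side, "bin_start": edges[:-1], "bin_end": edges[1:],
            "value": value, "n_features": counts[side].astype(int),
        }))
    return pd.concat(frames, ignore_index=True)


def relative_rate_profile(true_sites: pd.DataFrame,
                          potential_sites: pd.DataFrame,
                          features: pd.DataFrame,
                          inside: int = 0, outside: int = 100,
                          width: int = 20,
                          seed=0) -> pd.DataFrame:
    """Per-bin fraction of potential sites that are true sites.

    Also reports the companion profile of an equal-size random draw from
    the potential set (column ``value_random``); bins with no potential
    sites are missing.
    """
    true_keys = set(zip(true_sites["chrom"], true_sites["pos"]))
    pot_keys = set(zip(potential_sites["chrom"], potential_sites["pos"]))
    if not true_keys <= pot_keys:
        raise ValueError("true sites must be a subset of potential sites")
    rng = np.random.default_rng(seed)
    pot = potential_sites.copy()
    pot["value"] = [1.0 if k in true_keys else 0.0
                    for k in zip(pot["chrom"], pot["pos"])]
    profile = ends_metaplot(pot[["chrom", "pos", "value"]], features,
                            inside, outside, width)
    draw = rng.choice(len(pot), size=len(true_keys), replace=False)
    rand_keys = set(zip(pot.iloc[draw]["chrom"], pot.iloc[draw]["pos"]))
    pot["value"] = [1.0 if k in rand_keys else 0.0
                    for k in zip(pot["chrom"], pot["pos"])]
    rand_profile = ends_metaplot(pot[["chrom", "pos", "value"]], features,
                                 inside, outside, width)
    profile["value_random"] = rand_profile["value"]
    return profile


# ---------------------------------------------------------------------------
# sequence composition


def gc_content(genome, chrom: str, pos: int, window: int = 200) -> float:
    """Fraction of G/C bases in the window centered on the CG site."""
    seq = genome[chrom]
    half = window // 2
    sub = seq[max(pos - half, 0): pos + half]
    return sum(b in "GC" for b in sub) / len(sub) if sub else float("nan")


def cg_density(genome, chrom: str, pos: int, window: int = 200) -> int:
    """Count of CG dinucleotides in the window centered on the CG site."""
    seq = genome[chrom]
    half = window // 2
    sub = seq[max(pos - half, 0): pos + half + 1]
    return sub.count("CG")


_STAT_FUNCS = {"gc_content": gc_content, "cg_density": cg_density}


def composition_permutation_test(true_sites: pd.DataFrame,
                                 background_sites: pd.DataFrame,
                                 genome, stat: str = "gc_content",
                                 window: int = 200, n_perm: int = 10_000,
                                 seed=0,
                                 tail_cutoff: int = 100,
                                 ) -> CompositionTestResult:
    """Empirical two-tailed permutation test of local sequence composition.

    The statistic averaged over the true sites is compared with its average
    in ``n_perm`` equal-size random subsets of the background; a tail count
    below ``tail_cutoff`` is flagged significant.
    """
    if len(background_sites) < len(true_sites):
        raise ValueError("background smaller than the true set")
    func = _STAT_FUNCS[stat]
    rng = np.random.default_rng(seed)
    bg_vals = np.array([func(genome, c, p, window) for c, p in
                        zip(background_sites["chrom"],
                            background_sites["pos"])], dtype=float)
    true_vals = np.array([func(genome, c, p, window) for c, p in
                          zip(true_sites["chrom"], true_sites["pos"])],
                         dtype=float)
    observed = float(np.nanmean(true_vals))
    n_true = len(true_sites)
    perm_means = np.empty(n_perm)
    for i in range(n_perm):
        perm_means[i] = bg_vals[rng.choice(len(bg_vals), size=n_true,
                                           replace=False)].mean()
    right = int((perm_means > observed).sum())
    left = int((perm_means < observed).sum())
    return CompositionTestResult(
        observed, right, left, n_perm,
        p_right=right / n_perm, p_left=left / n_perm,
        significant=(right < tail_cutoff) or (left < tail_cutoff),
        tail_cutoff=tail_cutoff)


# ---------------------------------------------------------------------------
# small RNA overlap


def rpm_per_position(track: pd.DataFrame) -> dict:
    """Expand a bedGraph-style track into per-position RPM lookups."""
    lookup = {}
    for r in track.itertuples():
        for p in range(int(r.start), int(r.end)):
            key = (r.chrom, p)
            lookup[key] = lookup.get(key, 0.0) + float(r.value)
    return lookup


def srna_overlap(sites: pd.DataFrame, rpm_track: pd.DataFrame,
                 min_rpm: float = 1.0) -> tuple[pd.DataFrame, float]:
    """Mean RPM over a CG's two positions, overlap flag, group fraction."""
    lookup = rpm_per_position(rpm_track)
    values = [(lookup.get((c, p), 0.0) + lookup.get((c, p + 1), 0.0)) / 2.0
              for c, p in zip(sites["chrom"], sites["pos"])]
    out = sites[["chrom", "pos"]].copy()
    out["rpm"] = values
    out["overlaps"] = out["rpm"] >= min_rpm
    frac = float(out["overlaps"].mean()) if len(out) else float("nan")
    return out, frac
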