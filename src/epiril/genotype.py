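"""RIL genotype reconstruction from allele-tagged read depth.

Reads are assigned to parental haplotypes by the SNP alleles they overlap;
mean per-base depth of parent1-/parent2-assigned reads is tabulated on a
non-overlapping 200-bp grid, smoothed with a centered 51-window moving
average, thresholded into per-window calls, and merged into homozygous /
heterozygous / undetermined regions with iterative absorption of small
(<2 kb) regions flanked by larger regions of identical call.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

HOM1 = "hom1"
HOM2 = "hom2"
HET = "het"
UNDET = "undetermined"


def assign_read_alleles(basecalls, snp_table: pd.DataFrame) -> str:
    """Classify one read from its base calls at overlapped SNPs.

    ``basecalls`` is an iterable of (chrom, pos, base). SNPs where the base
    matches neither allele are ignored (sequencing-error tolerance). All
    informative SNPs agreeing on one parent give that parent; disagreement
    gives "conflicted"; no informative SNP gives "uninformative".
    """
    lookup = {(c, p): (a1, a2) for c, p, a1, a2 in zip(
        snp_table["chrom"], snp_table["pos"],
        snp_table["allele1"], snp_table["allele2"])}
    votes = set()
    for chrom, pos, base in basecalls:
        alleles = lookup.get((chrom, pos))
        if alleles is None:
            continue
        if base == alleles[0]:
            votes.add("parent1")
        elif base == alleles[1]:
            votes.add("parent2")
    if not votes:
        return "uninformative"
    if len(votes) > 1:
        return "conflicted"
    return votes.pop()


def assign_reads_table(read_basecalls: pd.DataFrame,
                       snp_table: pd.DataFrame) -> pd.Series:
    """Vector version: columns read_id, chrom, pos, base -> label per read."""
    labels = {}
    for read_id, grp in read_basecalls.groupby("read_id", sort=False):
        labels[read_id] = assign_read_alleles(
            zip(grp["chrom"], grp["pos"], grp["base"]), snp_table)
    return pd.Series(labels, name="label")


def smooth_depths(windows: pd.DataFrame, k: int = 51) -> pd.DataFrame:
    """Centered moving average of d1/d2 per chromosome (edges truncate)."""
    out = windows.sort_values(["chrom", "start"]).reset_index(drop=True).copy()
    grouped = out.groupby("chrom", sort=False)
    for col, scol in (("d1", "s1"), ("d2", "s2")):
        out[scol] = grouped[col].transform(
            lambda s: s.rolling(k, center=True, min_periods=1).mean())
    return out


def call_windows(windows: pd.DataFrame, min_depth: float = 2.0,
                 ratio: float = 1.5, diff: float = 2.0) -> pd.Series:
    """Per-window genotype calls from smoothed depths.

    Windows with combined smoothed depth below ``min_depth`` are
    undetermined. hom1 requires s1 > ratio*s2 and s1 - s2 > diff (mirror for
    hom2); het requires |s1 - s2| < diff with combined depth > min_depth.
    Windows with depth difference exactly ``diff`` fall to undetermined.
    """
    s1 = windows["s1"].to_numpy()
    s2 = windows["s2"].to_numpy()
    call = np.full(len(windows), UNDET, dtype=object)
    considered = (s1 + s2) >= min_depth
    call[considered & (s1 > ratio * s2) & (s1 - s2 > diff)] = HOM1
    call[considered & (s2 > ratio * s1) & (s2 - s1 > diff)] = HOM2
    het = considered & (np.abs(s1 - s2) < diff) & ((s1 + s2) > min_depth)
    call[het & (call == UNDET)] = HET
    return pd.Series(call, index=windows.index, name="call")


def _merge_adjacent(regions: list[list]) -> list[list]:
    merged = []
    for reg in regions:
        if merged and merged[-1][3] == reg[3] and merged[-1][2] == reg[1]:
            merged[-1][2] = reg[2]
        else:
            merged.append(list(reg))
    return merged


def merge_and_refine(window_calls: pd.DataFrame,
                     min_region: int = 2000,
                     max_iter: int = 1000) -> pd.DataFrame:
    """Merge window calls into regions and absorb small flanked regions.

    Iteratively, a region shorter than ``min_region`` whose nearest large
    (>= min_region) regions on both sides carry the same call is relabeled
    to that call; passes repeat until a fixed point. Regions tile each
    chromosome and adjacent regions end with different calls.
    """
    out_frames = []
    for chrom, grp in window_calls.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        regions = _merge_adjacent(
            [[chrom, int(r.start), int(r.end), r.call]
             for r in grp.itertuples()])
        for _ in range(max_iter):
            lengths = [r[2] - r[1] for r in regions]
            large = [i for i, ln in enumerate(lengths) if ln >= min_region]
            changed = False
            for i, reg in enumerate(regions):
                if lengths[i] >= min_region:
                    continue
                left = [j for j in large if j < i]
                right = [j for j in large if j > i]
                if not left or not right:
                    continue
                lcall = regions[left[-1]][3]
                rcall = regions[right[0]][3]
                if lcall == rcall and lcall != reg[3]:
                    reg[3] = lcall
                    changed = True
            regions = _merge_adjacent(regions)
            if not changed:
                break
        else:
            raise RuntimeError("merge_and_refine failed to converge")
        out_frames.append(pd.DataFrame(
            regions, columns=["chrom", "start", "end", "call"]))
    return pd.concat(out_frames, ignore_index=True)


def call_genotype_regions(window_depths: pd.DataFrame, k: int = 51,
                          min_depth: float = 2.0, ratio: float = 1.5,
                          diff: float = 2.0,
                          min_region: int = 2000) -> pd.DataFrame:
    """Full pipeline: smooth depths, call windows, merge and refine."""
    smoothed = smooth_depths(window_depths, k=k)
    calls = smoothed.copy()
    calls["call"] = call_windows(smoothed, min_depth, ratio, diff)
    return merge_and_refine(calls[["chrom", "start", "end", "call"]],
                            min_region=min_region)


def regions_to_bed(regions: pd.DataFrame) -> pd.DataFrame:
    bed = regions.rename(columns={"call": "name"}).copy()
    bed["score"] = 0
    return bed[["chrom", "start", "end", "name", "score"]]
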