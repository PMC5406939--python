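"""Replicate-consensus differential-cytosine caller and epimutation rates.

Differential methylation between two samples with two biological replicates
each is called per cytosine from all four replicate pairings: each pairing
contributes a significance score of +1 (sample 1 more methylated), -1, or 0
from a two-sided Fisher's exact test with per-pairing BH correction and a
context-dependent minimum level difference (CG/CHG > 0.40, CHH > 0.20). The
overall score is the sum over the four pairings; |score| >= 3 defines a
differential cytosine. Dynamic genic sites, potential gain/loss sets, gain
and loss rates and cross-set hypergeometric overlap tests build on this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import bh_adjust, fisher_exact_two_sided, hypergeom_upper_tail

MIN_DIFF_BY_CONTEXT = {"CG": 0.40, "CHG": 0.40, "CHH": 0.20}
CALL_S1 = "sample1_higher"
CALL_S2 = "sample2_higher"
CALL_NONE = "not_different"

POTENTIAL_GAIN_MAX = 0.60   # parent level <= 0.60 can gain
POTENTIAL_LOSS_MIN = 0.40   # parent level >= 0.40 can lose


class ContractViolation(ValueError):
    pass


def _align_counts(tables: list[pd.DataFrame]) -> tuple:
    """Inner-join count tables on (chrom, pos); returns index + count arrays."""
    indexed = [t.set_index(["chrom", "pos"])[["n_meth", "n_unmeth"]]
               for t in tables]
    common = indexed[0].index
    for t in indexed[1:]:
        common = common.intersection(t.index)
    common = common.sort_values()
    arrays = [(t.loc[common, "n_meth"].to_numpy(dtype=np.int64),
               t.loc[common, "n_unmeth"].to_numpy(dtype=np.int64))
              for t in indexed]
    return common, arrays


def pairwise_dmc(sample1_reps: list[pd.DataFrame],
                 sample2_reps: list[pd.DataFrame],
                 context: str = "CG", min_cov: int = 5,
                 alpha: float = 0.05,
                 min_diff: float | None = None) -> pd.DataFrame:
    """Per-site significance scores for sample1 vs sample2.

    Each sample contributes two replicate count tables (columns chrom, pos,
    n_meth, n_unmeth; for CG these are strand-merged records). Only sites
    with >= min_cov reads in every table enter the tests.
    """
    if len(sample1_reps) != 2 or len(sample2_reps) != 2:
        raise ContractViolation("two replicates per sample required")
    if min_diff is None:
        min_diff = MIN_DIFF_BY_CONTEXT[context]

    index, arrays = _align_counts(list(sample1_reps) + list(sample2_reps))
    cov_ok = np.ones(len(index), dtype=bool)
    for m, u in arrays:
        cov_ok &= (m + u) >= min_cov
    index = index[cov_ok]
    arrays = [(m[cov_ok], u[cov_ok]) for m, u in arrays]
    s1 = arrays[:2]
    s2 = arrays[2:]

    scores = np.zeros((len(index), 4), dtype=np.int64)
    for pair, ((m1, u1), (m2, u2)) in enumerate(
            (a, b) for a in s1 for b in s2):
        p_adj = bh_adjust(fisher_exact_two_sided(m1, u1, m2, u2))
        with np.errstate(invalid="ignore"):
            l1 = m1 / np.maximum(m1 + u1, 1)
            l2 = m2 / np.maximum(m2 + u2, 1)
        sig = (p_adj < alpha) & (np.abs(l1 - l2) > min_diff)
        scores[:, pair] = np.where(sig, np.sign(l1 - l2).astype(int), 0)

    overall = scores.sum(axis=1)
    call = np.full(len(index), CALL_NONE, dtype=object)
    call[overall >= 3] = CALL_S1
    call[overall <= -3] = CALL_S2
    out = pd.DataFrame({
        "chrom": index.get_level_values("chrom"),
        "pos": index.get_level_values("pos").astype(np.int64),
        "score_1": scores[:, 0], "score_2": scores[:, 1],
        "score_3": scores[:, 2], "score_4": scores[:, 3],
        "overall": overall, "call": call,
    })
    return out


@dataclass
class DynamicSiteSets:
    """Dynamic and potential gain/loss site sets for one RIL genotype."""
    genotype: str                     # "hom1" (parent1-derived) or "hom2"
    gain: pd.Index
    loss: pd.Index
    potential_gain: pd.Index
    potential_loss: pd.Index
    scores: pd.DataFrame = field(repr=False, default=None)


def _keys(df: pd.DataFrame) -> pd.Index:
    return pd.MultiIndex.from_arrays([df["chrom"], df["pos"]],
                                     names=["chrom", "pos"])


def _in_intervals(df: pd.DataFrame, intervals: pd.DataFrame,
                  width: int = 1) -> np.ndarray:
    """True where [pos, pos+width) intersects an interval (per chromosome)."""
    hit = np.zeros(len(df), dtype=bool)
    for chrom, grp in intervals.groupby("chrom"):
        m = (df["chrom"] == chrom).to_numpy()
        if not m.any():
            continue
        pos = df.loc[m, "pos"].to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        idx = np.searchsorted(starts, pos + width, side="left") - 1
        ok = idx >= 0
        sub = np.zeros(len(pos), dtype=bool)
        sub[ok] = pos[ok] < ends[idx[ok]]
        hit[m] = sub
    return hit


def call_dynamic_sites(ril_reps: list[pd.DataFrame],
                       parent_reps: dict[str, list[pd.DataFrame]],
                       genotype_regions: pd.DataFrame,
                       genes: pd.DataFrame,
                       tes: pd.DataFrame | None = None,
                       min_cov: int = 5, alpha: float = 0.05,
                       ) -> dict[str, DynamicSiteSets]:
    """Dynamic genic CG sites per parental genotype.

    For each homozygous genotype the RIL replicates are compared against the
    matching parent's replicates over genic CGs (TSS-TTS, excluding CGs
    whose dinucleotide overlaps an annotated TE) inside regions of that
    call. Gain = RIL more methylated; loss = parent more methylated.
    Potential gain/loss sets are the tested sites whose pooled parent level
    is <= 0.60 / >= 0.40. Sites in heterozygous or undetermined regions are
    excluded.
    """
    results = {}
    for genotype in ("hom1", "hom2"):
        regions = genotype_regions[genotype_regions["call"] == genotype]
        scores = pairwise_dmc(ril_reps, parent_reps[genotype],
                              context="CG", min_cov=min_cov, alpha=alpha)
        keep = _in_intervals(scores, regions) \
            & _in_intervals(scores, genes)
        if tes is not None and not tes.empty:
            keep &= ~_in_intervals(scores, tes, width=2)
        scores = scores[keep].reset_index(drop=True)

        # pooled parent level over both replicates at the tested sites
        pidx, parrays = _align_counts(list(parent_reps[genotype]))
        pm = sum(a[0] for a in parrays)
        pu = sum(a[1] for a in parrays)
        plevel = pd.Series(pm / np.maximum(pm + pu, 1), index=pidx)
        skeys = _keys(scores)
        parent_level = plevel.reindex(skeys).to_numpy()
        scores["parent_level"] = parent_level

        potential_gain = skeys[parent_level <= POTENTIAL_GAIN_MAX]
        potential_loss = skeys[parent_level >= POTENTIAL_LOSS_MIN]
        gain = skeys[(scores["call"] == CALL_S1).to_numpy()
                     & (parent_level <= POTENTIAL_GAIN_MAX)]
        loss = skeys[(scores["call"] == CALL_S2).to_numpy()
                     & (parent_level >= POTENTIAL_LOSS_MIN)]
        results[genotype] = DynamicSiteSets(
            genotype, gain, loss, potential_gain, potential_loss, scores)
    return results


def gain_loss_rates(sets: DynamicSiteSets) -> dict:
    """Gain/loss rates (percent of potential sites) and loss/gain ratio."""
    if len(sets.potential_gain) == 0 or len(sets.potential_loss) == 0:
        raise ContractViolation("potential site sets must be non-empty")
    rate_gain = 100.0 * len(sets.gain) / len(sets.potential_gain)
    rate_loss = 100.0 * len(sets.loss) / len(sets.potential_loss)
    ratio = rate_loss / rate_gain if rate_gain > 0 else float("nan")
    return {"rate_gain": rate_gain, "rate_loss": rate_loss, "ratio": ratio,
            "ratio_defined": rate_gain > 0}


def overlap_significance(set_a, set_b, universe) -> float:
    """Upper-tail hypergeometric p for the overlap of two site sets."""
    set_a, set_b = set(set_a), set(set_b)
    universe = set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ContractViolation("sets must be subsets of the universe")
    k = len(set_a & set_b)
    return hypergeom_upper_tail(k, len(universe), len(set_a), len(set_b))
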