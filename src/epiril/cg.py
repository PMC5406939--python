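"""Symmetric-CG processing.

CG methylation is maintained symmetrically on the two strands, so the two
cytosines of a CG dinucleotide are treated as a single record: strand counts
are pooled after a per-site consistency test (two-sided Fisher's exact test
with BH correction; sites where the corrected p < alpha AND the strand
levels differ by more than 40 points are censored as inconsistent).
Cytosines overlapping known SNPs are censored, and weighted methylation
levels, per-site parent-vs-parent categories and per-gene category fractions
are computed from the merged records.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._stats import bh_adjust, fisher_exact_two_sided

STATUS_MERGED = "merged"
STATUS_INCONSISTENT = "censored_inconsistent"
STATUS_SNP = "censored_snp"
STATUS_SINGLE = "single_strand"

CORNER_ORDER = ["both_low", "p1_only", "p2_only", "both_high"]


class InsufficientDataError(ValueError):
    """Too few observations for the requested statistic."""


def merge_strand_table(cytosines: pd.DataFrame, alpha: float = 0.05,
                       min_diff: float = 0.40) -> pd.DataFrame:
    """Merge a stranded cytosine table into one record per CG dinucleotide.

    Non-CG records are ignored (they pass through downstream unmerged).
    Returns columns chrom, pos (forward-strand C), n_meth, n_unmeth, level,
    status, p_adj. The BH correction runs across all CGs tested in the
    table, i.e. per sample.
    """
    cg = cytosines[cytosines["context"] == "CG"].copy()
    if (cg["strand"] == "-").any():
        cg.loc[cg["strand"] == "-", "pos"] -= 1
    wide = cg.pivot_table(index=["chrom", "pos"], columns="strand",
                          values=["n_meth", "n_unmeth"], aggfunc="sum")
    for col in [("n_meth", "+"), ("n_meth", "-"),
                ("n_unmeth", "+"), ("n_unmeth", "-")]:
        if col not in wide.columns:
            wide[col] = np.nan
    mf = wide[("n_meth", "+")].to_numpy()
    uf = wide[("n_unmeth", "+")].to_numpy()
    mr = wide[("n_meth", "-")].to_numpy()
    ur = wide[("n_unmeth", "-")].to_numpy()
    has_fw = ~np.isnan(mf)
    has_rv = ~np.isnan(mr)
    both = has_fw & has_rv

    mf0, uf0 = np.nan_to_num(mf), np.nan_to_num(uf)
    mr0, ur0 = np.nan_to_num(mr), np.nan_to_num(ur)
    p_adj = np.full(len(wide), np.nan)
    if both.any():
        p = fisher_exact_two_sided(mf0[both].astype(int), uf0[both].astype(int),
                                   mr0[both].astype(int), ur0[both].astype(int))
        p_adj[both] = bh_adjust(p)
    with np.errstate(invalid="ignore", divide="ignore"):
        lvl_f = mf0 / (mf0 + uf0)
        lvl_r = mr0 / (mr0 + ur0)
    inconsistent = both & (p_adj < alpha) \
        & (np.abs(lvl_f - lvl_r) > min_diff)

    n_meth = (mf0 + mr0).astype(np.int64)
    n_unmeth = (uf0 + ur0).astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        level = n_meth / np.maximum(n_meth + n_unmeth, 1)
    status = np.where(both, STATUS_MERGED, STATUS_SINGLE)
    status = np.where(inconsistent, STATUS_INCONSISTENT, status)
    level = np.where(inconsistent, np.nan, level)

    out = pd.DataFrame({
        "chrom": wide.index.get_level_values("chrom"),
        "pos": wide.index.get_level_values("pos").astype(np.int64),
        "n_meth": n_meth, "n_unmeth": n_unmeth,
        "level": level, "status": status, "p_adj": p_adj,
    })
    return out.sort_values(["chrom", "pos"]).reset_index(drop=True)


def merge_symmetric_cg(fw: tuple, rv_counts: tuple, p_adj: float,
                       alpha: float = 0.05, min_diff: float = 0.40) -> dict:
    """Single-site merge given already-corrected p (scalar convenience)."""
    mf, uf = fw
    mr, ur = rv_counts
    lvl_f = mf / (mf + uf) if mf + uf else np.nan
    lvl_r = mr / (mr + ur) if mr + ur else np.nan
    if p_adj < alpha and abs(lvl_f - lvl_r) > min_diff:
        return {"status": STATUS_INCONSISTENT, "level": np.nan,
                "n_meth": mf + mr, "n_unmeth": uf + ur}
    total = mf + mr + uf + ur
    return {"status": STATUS_MERGED,
            "level": (mf + mr) / total if total else np.nan,
            "n_meth": mf + mr, "n_unmeth": uf + ur}


def censor_snp_overlaps(sites: pd.DataFrame,
                        snp_table: pd.DataFrame) -> pd.DataFrame:
    """Censor records whose cytosine position(s) coincide with a SNP.

    For merged CG records (no ``strand`` column) both positions of the
    dinucleotide, pos and pos+1, are checked; for stranded records only the
    record's own position.
    """
    out = sites.copy()
    if snp_table is None or snp_table.empty:
        return out
    snp_keys = set(zip(snp_table["chrom"], snp_table["pos"]))
    first = [(c, p) in snp_keys for c, p in zip(out["chrom"], out["pos"])]
    hit = np.asarray(first)
    if "strand" not in out.columns:
        second = [(c, p + 1) in snp_keys
                  for c, p in zip(out["chrom"], out["pos"])]
        hit = hit | np.asarray(second)
        out.loc[hit, "status"] = STATUS_SNP
        out.loc[hit, "level"] = np.nan
    else:
        out["censored_snp"] = hit
    return out


def usable(merged: pd.DataFrame) -> pd.DataFrame:
    """Merged CG records usable downstream (not censored, both strands)."""
    return merged[merged["status"] == STATUS_MERGED]


def weighted_methylation(sites: pd.DataFrame, region: tuple | None = None,
                         min_cov: int = 5, min_sites: int = 5) -> float:
    """Weighted methylation over a region: sum meth / sum total reads.

    Only sites with coverage >= min_cov qualify; the value is missing (NaN)
    when fewer than min_sites sites qualify.
    """
    sub = usable(sites) if "status" in sites.columns else sites
    if region is not None:
        chrom, start, end = region
        sub = sub[(sub["chrom"] == chrom) & (sub["pos"] >= start)
                  & (sub["pos"] < end)]
    cov = sub["n_meth"] + sub["n_unmeth"]
    sub = sub[cov >= min_cov]
    if len(sub) < min_sites:
        return float("nan")
    total = (sub["n_meth"] + sub["n_unmeth"]).sum()
    return float(sub["n_meth"].sum() / total) if total else float("nan")


def weighted_methylation_by_gene(sites: pd.DataFrame, genes: pd.DataFrame,
                                 min_cov: int = 5,
                                 min_sites: int = 5) -> pd.Series:
    """Per-gene weighted methylation level keyed by the BED name field."""
    values = {}
    for r in genes.itertuples():
        values[r.name] = weighted_methylation(
            sites, (r.chrom, r.start, r.end), min_cov, min_sites)
    return pd.Series(values, name="level")


def categorize_sites(p1_levels, p2_levels, low: float = 0.20,
                     high: float = 0.80):
    """Per-site parental category and summary fractions.

    Categories: both_low (both <= low), both_high (both >= high), p1_only
    (p1 >= high, p2 <= low), p2_only (mirror), else intermediate. Fractions
    are over all sites with data in both parents.
    """
    p1 = np.asarray(p1_levels, dtype=float)
    p2 = np.asarray(p2_levels, dtype=float)
    ok = ~(np.isnan(p1) | np.isnan(p2))
    cat = np.full(len(p1), "intermediate", dtype=object)
    cat[ok & (p1 <= low) & (p2 <= low)] = "both_low"
    cat[ok & (p1 >= high) & (p2 >= high)] = "both_high"
    cat[ok & (p1 >= high) & (p2 <= low)] = "p1_only"
    cat[ok & (p2 >= high) & (p1 <= low)] = "p2_only"
    cat[~ok] = None
    n = int(ok.sum())
    fractions = {name: float((cat == name).sum() / n) if n else float("nan")
                 for name in CORNER_ORDER + ["intermediate"]}
    return pd.Series(cat, name="category"), fractions


def gene_category_fractions(site_categories: pd.DataFrame,
                            genes: pd.DataFrame,
                            min_classified: int = 10) -> pd.DataFrame:
    """Per-gene fraction of classified (corner) CGs in each corner.

    ``site_categories`` needs chrom, pos, category columns. Genes with fewer
    than ``min_classified`` corner-classified CGs are omitted.
    """
    classified = site_categories[
        site_categories["category"].isin(CORNER_ORDER)]
    rows = {}
    for r in genes.itertuples():
        sub = classified[(classified["chrom"] == r.chrom)
                         & (classified["pos"] >= r.start)
                         & (classified["pos"] < r.end)]
        if len(sub) < min_classified:
            continue
        counts = sub["category"].value_counts()
        rows[r.name] = [counts.get(c, 0) / len(sub) for c in CORNER_ORDER]
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=CORNER_ORDER)


def replicate_correlation(levels_a: pd.Series, levels_b: pd.Series) -> float:
    """Pearson correlation of per-site levels over sites with data in both."""
    joined = pd.concat([levels_a, levels_b], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise InsufficientDataError(
            f"only {len(joined)} shared sites; need >= 3")
    return float(np.corrcoef(joined.iloc[:, 0], joined.iloc[:, 1])[0, 1])
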