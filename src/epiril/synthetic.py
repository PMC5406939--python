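"""Synthetic bisulfite data with planted ground truth.

Emulates the data regime of a two-parent recombinant-inbred-line (RIL)
methylation study: two parental methylomes that diverge in gene-body CG
methylation (one parent hypomethylated at a subset of genic CGs), mosaic RIL
genomes assembled from exponential-length parental segments, RIL methylomes
with planted gain/loss epimutations concentrated where local methylation is
intermediate, allele-tagged read-depth tracks for genotype reconstruction,
small-RNA coverage tracks, and a sites-by-strains methylation panel drawn
from known variability archetypes.

Counts are drawn per strand as Binomial(depth, true level) with Poisson
depths; no read-level sequence is simulated. All coordinates are 0-based,
half-open; a CG dinucleotide is indexed by its forward-strand C at ``pos``,
with the reverse-strand C at ``pos + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

BINS6 = ["invariant_low", "invariant_high", "bimodal_low", "bimodal_med",
         "bimodal_high", "distributed"]

HIGH_LEVEL = 0.9
LOW_LEVEL = 0.05


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class DependencyError(RuntimeError):
    """A required upstream simulation product is missing."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults are scaled-down but structurally faithful: two chromosomes with
    ~100 genes, sequencing depth 20 per strand, a 50-strain panel standing in
    for a large natural-accession panel, per-generation-scale epimutation
    rates of order 1%, and an enrichment multiplier concentrating planted
    dynamic sites where the surrounding 200 bp has intermediate methylation.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 400_000
    n_genes: int = 120
    gene_length_range: tuple = (1500, 4000)
    cg_spacing_mean: float = 60.0       # mean bp between genic CG sites
    depth_mean: float = 20.0            # mean read depth per strand
    n_strains_panel: int = 50
    n_panel_sites: int = 3000
    parent1_meth_profile: object = None  # optional per-gene mean levels
    parent2_meth_profile: object = None
    frac_genes_methylated: float = 0.35  # body-methylated genes in parent 1
    frac_hypomethylated_in_parent2: float = 0.5
    frac_genes_methylated_only_p2: float = 0.03
    meth_site_density: float = 0.6      # high-CG fraction inside a gbM gene
    epimutation_gain_rate: float = 0.01
    epimutation_loss_rate: float = 0.01
    enrichment_at_intermediate: float = 15.0
    segment_length_mean: float = 100_000.0  # RIL mosaic block length
    snp_density: float = 2.0            # SNPs per kb
    srna_cluster_rate: float = 20.0     # background clusters per Mb
    srna_gain_overlap_frac: float = 0.2  # trans-sRNA overlap of gain sites
    misassignment_rate: float = 0.05    # allele-tagged read noise
    expression_lognormal_params: tuple = (1.0, 1.0)
    panel_noise_sd: float = 0.05
    panel_missing_frac: float = 0.1
    window_size: int = 200

    def __post_init__(self):
        for name in ("frac_genes_methylated", "frac_hypomethylated_in_parent2",
                     "frac_genes_methylated_only_p2", "meth_site_density",
                     "epimutation_gain_rate", "epimutation_loss_rate",
                     "srna_gain_overlap_frac", "misassignment_rate",
                     "panel_missing_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.depth_mean <= 0:
            raise ConfigurationError("depth_mean must be positive")
        if self.chromosome_length <= 0 or self.segment_length_mean <= 0:
            raise ConfigurationError("lengths must be positive")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo or hi >= self.chromosome_length:
            raise ConfigurationError("invalid gene_length_range")
        if self.enrichment_at_intermediate < 1.0:
            raise ConfigurationError("enrichment_at_intermediate must be >= 1")


@dataclass
class SimulatedParents:
    config: SimulationConfig
    genes: pd.DataFrame       # BED6
    tes: pd.DataFrame         # BED6
    snps: pd.DataFrame        # chrom, pos, allele1, allele2
    sites: pd.DataFrame       # per cytosine site: true levels + annotation
    parent1: pd.DataFrame     # stranded cytosine table, replicate 1
    parent2: pd.DataFrame
    expression: pd.DataFrame  # gene, fpkm
    parent1_rep2: pd.DataFrame = None  # sibling biological replicates
    parent2_rep2: pd.DataFrame = None

    @property
    def parent_reps(self) -> dict:
        """Replicate pairs keyed by the genotype label they correspond to."""
        return {"hom1": [self.parent1, self.parent1_rep2],
                "hom2": [self.parent2, self.parent2_rep2]}


@dataclass
class SimulatedRIL:
    ril_id: int
    segments: pd.DataFrame      # chrom, start, end, label (hom1/hom2)
    sites: pd.DataFrame         # per site: origin, true_level
    dynamic: pd.DataFrame       # chrom, pos, direction (gain/loss)
    rep1: pd.DataFrame
    rep2: pd.DataFrame
    window_depths: pd.DataFrame  # chrom, start, end, d1, d2
    srna_parent1: pd.DataFrame   # bedGraph-style RPM tracks
    srna_parent2: pd.DataFrame


@dataclass
class SimulatedPanel:
    levels: pd.DataFrame    # sites x strains
    coverage: pd.DataFrame
    truth: pd.Series        # class6 archetype per site
    sites: pd.DataFrame


# ---------------------------------------------------------------------------
# parents


def _chrom_names(config):
    return [f"chr{i + 1}" for i in range(config.n_chromosomes)]


def _place_genes(config, rng) -> pd.DataFrame:
    chroms = _chrom_names(config)
    per = np.full(len(chroms), config.n_genes // len(chroms))
    per[: config.n_genes % len(chroms)] += 1
    rows = []
    gi = 0
    for chrom, n in zip(chroms, per):
        slot = config.chromosome_length // max(n, 1)
        for j in range(n):
            length = int(rng.integers(*config.gene_length_range))
            start = j * slot + int(rng.integers(0, max(slot - length, 1)))
            rows.append((chrom, start, start + length, f"gene{gi:04d}", 0,
                         "+" if rng.random() < 0.5 else "-"))
            gi += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand"])


def _place_tes(config, rng) -> pd.DataFrame:
    rows = []
    n_te = max(4, config.n_genes // 5)
    for ti in range(n_te):
        chrom = _chrom_names(config)[int(rng.integers(config.n_chromosomes))]
        length = int(rng.integers(300, 1000))
        start = int(rng.integers(0, config.chromosome_length - length))
        rows.append((chrom, start, start + length, f"te{ti:03d}", 0, "+"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand"]).sort_values(
        ["chrom", "start"]).reset_index(drop=True)


def _interval_positions(start, end, spacing, rng, min_gap=2):
    """Positions in [start, end) with ~exponential spacing, >= min_gap apart."""
    n_est = max(int((end - start) / spacing * 2) + 4, 4)
    gaps = min_gap + rng.exponential(max(spacing - min_gap, 1.0), size=n_est)
    pos = start + np.cumsum(gaps).astype(np.int64)
    return pos[pos < end - 2]


def _overlaps(positions: np.ndarray, intervals: pd.DataFrame,
              chrom: str, width: int = 2) -> np.ndarray:
    """True where [pos, pos+width) intersects any interval on ``chrom``."""
    sub = intervals[intervals["chrom"] == chrom]
    if sub.empty or len(positions) == 0:
        return np.zeros(len(positions), dtype=bool)
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    idx = np.searchsorted(starts, positions + width, side="left") - 1
    hit = np.zeros(len(positions), dtype=bool)
    # an interval other than the nearest-left one could still overlap if
    # intervals nest; for the generated non-nested intervals this suffices
    ok = idx >= 0
    hit[ok] = positions[ok] < ends[idx[ok]]
    return hit


def _gene_index(positions: np.ndarray, genes: pd.DataFrame,
                chrom: str) -> np.ndarray:
    sub = genes[genes["chrom"] == chrom].sort_values("start")
    out = np.full(len(positions), -1, dtype=np.int64)
    if sub.empty:
        return out
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    idx = np.searchsorted(starts, positions, side="right") - 1
    ok = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
    out[ok] = sub.index.to_numpy()[idx[ok]]
    return out


def simulate_parents(config: SimulationConfig) -> SimulatedParents:
    """Generate annotations, SNPs and the two parental methylomes."""
    rng = np.random.default_rng([config.seed, 1])
    genes = _place_genes(config, rng)
    tes = _place_tes(config, rng)

    # per-gene methylation status in each parent
    n_genes = len(genes)
    if config.parent1_meth_profile is not None:
        p1_mean = np.asarray(config.parent1_meth_profile, dtype=float)
        p2_mean = np.asarray(
            config.parent2_meth_profile
            if config.parent2_meth_profile is not None
            else config.parent1_meth_profile, dtype=float)
        if len(p1_mean) != n_genes or len(p2_mean) != n_genes:
            raise ConfigurationError("meth profile length != n_genes")
        p1_density = np.clip(p1_mean / HIGH_LEVEL, 0, 1)
        p2_density = np.clip(p2_mean / HIGH_LEVEL, 0, 1)
    else:
        meth1 = rng.random(n_genes) < config.frac_genes_methylated
        hypo = meth1 & (rng.random(n_genes)
                        < config.frac_hypomethylated_in_parent2)
        p2only = ~meth1 & (rng.random(n_genes)
                           < config.frac_genes_methylated_only_p2)
        p1_density = np.where(meth1, config.meth_site_density, 0.0)
        p2_density = np.where(meth1 & ~hypo, config.meth_site_density, 0.0)
        p2_density = np.where(p2only, config.meth_site_density, p2_density)

    site_rows = []
    for chrom in _chrom_names(config):
        gsub = genes[genes["chrom"] == chrom]
        # genic CG sites, dense; intergenic CG sites, sparser
        cg_pos = [
            _interval_positions(r.start, r.end, config.cg_spacing_mean, rng)
            for r in gsub.itertuples()
        ]
        inter = []
        prev = 0
        for r in gsub.itertuples():
            if r.start > prev:
                inter.append(_interval_positions(
                    prev, r.start, config.cg_spacing_mean * 4, rng))
            prev = max(prev, r.end)
        if prev < config.chromosome_length:
            inter.append(_interval_positions(
                prev, config.chromosome_length, config.cg_spacing_mean * 4, rng))
        all_cg = np.sort(np.concatenate(cg_pos + inter)) if (cg_pos or inter) \
            else np.array([], dtype=np.int64)
        all_cg = all_cg[np.diff(all_cg, prepend=-10) >= 2]
        df = pd.DataFrame({"chrom": chrom, "pos": all_cg, "context": "CG"})
        # non-CG cytosines, sparser still, single strand each
        taken = np.concatenate([all_cg, all_cg + 1])
        for ctx, mult in (("CHG", 3.0), ("CHH", 2.0)):
            pos = _interval_positions(0, config.chromosome_length,
                                      config.cg_spacing_mean * mult, rng)
            pos = pos[~np.isin(pos, taken)]
            taken = np.concatenate([taken, pos])
            df = pd.concat([df, pd.DataFrame(
                {"chrom": chrom, "pos": pos, "context": ctx})])
        site_rows.append(df)
    sites = pd.concat(site_rows, ignore_index=True)
    sites = sites.sort_values(["chrom", "pos"]).reset_index(drop=True)

    gene_idx = np.full(len(sites), -1, dtype=np.int64)
    te_flag = np.zeros(len(sites), dtype=bool)
    for chrom in _chrom_names(config):
        m = (sites["chrom"] == chrom).to_numpy()
        pos = sites.loc[m, "pos"].to_numpy()
        gene_idx[m] = _gene_index(pos, genes, chrom)
        te_flag[m] = _overlaps(pos, tes, chrom)
    sites["gene_idx"] = gene_idx
    sites["te"] = te_flag
    sites["genic"] = gene_idx >= 0

    # true levels
    is_cg = (sites["context"] == "CG").to_numpy()
    u = rng.random(len(sites))
    p1 = np.full(len(sites), LOW_LEVEL)
    p2 = np.full(len(sites), LOW_LEVEL)
    genic_cg = is_cg & sites["genic"].to_numpy()
    gidx = sites["gene_idx"].to_numpy()
    hi1 = genic_cg & (u < np.where(gidx >= 0, p1_density[np.clip(gidx, 0, None)], 0))
    hi2 = genic_cg & (u < np.where(gidx >= 0, p2_density[np.clip(gidx, 0, None)], 0))
    p1[hi1] = HIGH_LEVEL
    p2[hi2] = HIGH_LEVEL
    te_cg = is_cg & te_flag
    p1[te_cg] = HIGH_LEVEL
    p2[te_cg] = HIGH_LEVEL
    noncg_te = ~is_cg & te_flag
    p1[noncg_te] = 0.5
    p2[noncg_te] = 0.5
    jitter = rng.normal(0.0, 0.02, size=len(sites))
    sites["p1_level"] = np.clip(p1 + jitter, 0, 1)
    sites["p2_level"] = np.clip(p2 + jitter, 0, 1)
    strand_choice = np.where(rng.random(len(sites)) < 0.5, "+", "-")
    sites["noncg_strand"] = np.where(is_cg, "+", strand_choice)

    # SNPs: uniform positions at snp_density per kb, alleles random
    snp_rows = []
    for chrom in _chrom_names(config):
        n_snp = rng.poisson(config.snp_density
                            * config.chromosome_length / 1000.0)
        pos = np.sort(rng.choice(config.chromosome_length, size=n_snp,
                                 replace=False))
        bases = np.array(list("ACGT"))
        a1 = bases[rng.integers(0, 4, size=n_snp)]
        shift = rng.integers(1, 4, size=n_snp)
        a2 = bases[(np.searchsorted(bases, a1) + shift) % 4]
        snp_rows.append(pd.DataFrame(
            {"chrom": chrom, "pos": pos, "allele1": a1, "allele2": a2}))
    snps = pd.concat(snp_rows, ignore_index=True)

    parent1 = _stranded_counts(sites, "p1_level", config.depth_mean,
                               np.random.default_rng([config.seed, 11]))
    parent2 = _stranded_counts(sites, "p2_level", config.depth_mean,
                               np.random.default_rng([config.seed, 12]))
    parent1_rep2 = _stranded_counts(sites, "p1_level", config.depth_mean,
                                    np.random.default_rng([config.seed, 13]))
    parent2_rep2 = _stranded_counts(sites, "p2_level", config.depth_mean,
                                    np.random.default_rng([config.seed, 14]))

    mu, sigma = config.expression_lognormal_params
    expression = pd.DataFrame({
        "gene": genes["name"],
        "fpkm": rng.lognormal(mu, sigma, size=n_genes),
    })
    return SimulatedParents(config, genes, tes, snps, sites,
                            parent1, parent2, expression,
                            parent1_rep2, parent2_rep2)


def _stranded_counts(sites: pd.DataFrame, level_col: str, depth_mean: float,
                     rng) -> pd.DataFrame:
    """Draw a stranded cytosine count table from true levels.

    CG sites yield one record per strand (forward C at pos, reverse C at
    pos+1) sharing the site's true level; non-CG sites yield one record on
    their assigned strand. Zero-depth records are dropped (no data).
    """
    is_cg = (sites["context"] == "CG").to_numpy()
    levels = sites[level_col].to_numpy()
    frames = []
    for strand_sel in ("+", "-"):
        if strand_sel == "+":
            mask = is_cg | (sites["noncg_strand"] == "+").to_numpy()
            pos = sites["pos"].to_numpy()[mask]
        else:
            mask = is_cg | (sites["noncg_strand"] == "-").to_numpy()
            pos = sites["pos"].to_numpy()[mask] + np.where(
                is_cg[mask], 1, 0)
        depth = rng.poisson(depth_mean, size=mask.sum())
        n_meth = rng.binomial(depth, levels[mask])
        frames.append(pd.DataFrame({
            "chrom": sites["chrom"].to_numpy()[mask],
            "pos": pos,
            "strand": strand_sel,
            "n_meth": n_meth,
            "n_unmeth": depth - n_meth,
            "context": sites["context"].to_numpy()[mask],
        }))
    out = pd.concat(frames, ignore_index=True)
    out = out[out["n_meth"] + out["n_unmeth"] > 0]
    return out.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# RIL


def simulate_segments(config: SimulationConfig, rng) -> pd.DataFrame:
    """Alternating parental mosaic blocks with exponential lengths."""
    rows = []
    for chrom in _chrom_names(config):
        pos = 0
        label = "hom1" if rng.random() < 0.5 else "hom2"
        while pos < config.chromosome_length:
            length = max(int(rng.exponential(config.segment_length_mean)), 1000)
            end = min(pos + length, config.chromosome_length)
            rows.append((chrom, pos, end, label))
            pos = end
            label = "hom2" if label == "hom1" else "hom1"
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


def _segment_labels(segments: pd.DataFrame, chrom: str,
                    positions: np.ndarray) -> np.ndarray:
    sub = segments[segments["chrom"] == chrom].sort_values("start")
    idx = np.searchsorted(sub["start"].to_numpy(), positions, side="right") - 1
    return sub["label"].to_numpy()[np.clip(idx, 0, None)]


def local_mean_level(positions: np.ndarray, levels: np.ndarray,
                     window: int = 200) -> np.ndarray:
    """Mean level of neighbors within +-window/2 bp, excluding the site."""
    half = window // 2
    order = np.argsort(positions)
    pos_s = positions[order]
    lev_s = levels[order]
    csum = np.concatenate([[0.0], np.cumsum(lev_s)])
    lo = np.searchsorted(pos_s, pos_s - half, side="left")
    hi = np.searchsorted(pos_s, pos_s + half, side="right")
    total = csum[hi] - csum[lo] - lev_s
    count = hi - lo - 1
    out = np.full(len(pos_s), np.nan)
    nz = count > 0
    out[nz] = total[nz] / count[nz]
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    return out[inv]


def simulate_ril(config: SimulationConfig, parents: SimulatedParents,
                 ril_id: int = 1) -> SimulatedRIL:
    """Mosaic genome, planted dynamic sites and two replicate methylomes."""
    if parents is None:
        raise DependencyError("simulate_parents output required")
    rng = np.random.default_rng([config.seed, 2, ril_id])
    segments = simulate_segments(config, rng)

    sites = parents.sites.copy()
    origin = np.empty(len(sites), dtype=object)
    for chrom in _chrom_names(config):
        m = (sites["chrom"] == chrom).to_numpy()
        origin[m] = _segment_labels(segments, chrom,
                                    sites.loc[m, "pos"].to_numpy())
    sites["origin"] = origin
    parent_level = np.where(origin == "hom1",
                            sites["p1_level"], sites["p2_level"])
    true_level = parent_level.copy()

    # plant dynamic sites among eligible genic, TE-free CG sites;
    # enrichment applies where the surrounding 200 bp of the parent-of-origin
    # methylome has intermediate mean methylation
    is_cg = (sites["context"] == "CG").to_numpy()
    eligible = is_cg & sites["genic"].to_numpy() & ~sites["te"].to_numpy()
    local = np.full(len(sites), np.nan)
    for chrom in _chrom_names(config):
        m = ((sites["chrom"] == chrom) & is_cg).to_numpy()
        local[m] = local_mean_level(sites.loc[m, "pos"].to_numpy(),
                                    parent_level[m], config.window_size)
    intermediate = (local >= 0.2) & (local <= 0.8)
    mult = np.where(intermediate, config.enrichment_at_intermediate, 1.0)
    p_gain = np.clip(config.epimutation_gain_rate * mult, 0, 1)
    p_loss = np.clip(config.epimutation_loss_rate * mult, 0, 1)
    can_gain = eligible & (parent_level <= 0.6)
    can_loss = eligible & (parent_level >= 0.4)
    gain = can_gain & (rng.random(len(sites)) < p_gain)
    loss = can_loss & ~gain & (rng.random(len(sites)) < p_loss)
    true_level = np.where(gain, np.minimum(1.0, parent_level + 0.5), true_level)
    true_level = np.where(loss, np.maximum(0.0, parent_level - 0.5), true_level)
    sites["true_level"] = true_level

    dyn = pd.concat([
        pd.DataFrame({"chrom": sites.loc[gain, "chrom"],
                      "pos": sites.loc[gain, "pos"], "direction": "gain"}),
        pd.DataFrame({"chrom": sites.loc[loss, "chrom"],
                      "pos": sites.loc[loss, "pos"], "direction": "loss"}),
    ], ignore_index=True).sort_values(["chrom", "pos"]).reset_index(drop=True)

    rep1 = _stranded_counts(sites, "true_level", config.depth_mean,
                            np.random.default_rng([config.seed, 21, ril_id]))
    rep2 = _stranded_counts(sites, "true_level", config.depth_mean,
                            np.random.default_rng([config.seed, 22, ril_id]))

    window_depths = simulate_window_depths(config, segments, rng)
    srna1, srna2 = _simulate_srna(config, sites, gain, rng)
    return SimulatedRIL(ril_id, segments, sites, dyn, rep1, rep2,
                        window_depths, srna1, srna2)


def simulate_window_depths(config: SimulationConfig, segments: pd.DataFrame,
                           rng) -> pd.DataFrame:
    """Allele-tagged mean read depth on the 200-bp genotyping grid.

    The window's true parent receives Poisson(depth * (1 - noise)) depth and
    the other parent Poisson(depth * noise), emulating a small fraction of
    misassigned reads.
    """
    w = config.window_size
    frames = []
    for chrom in _chrom_names(config):
        starts = np.arange(0, config.chromosome_length, w)
        labels = _segment_labels(segments, chrom, starts + w // 2)
        is1 = labels == "hom1"
        d_true = rng.poisson(config.depth_mean
                             * (1 - config.misassignment_rate), len(starts))
        d_other = rng.poisson(config.depth_mean
                              * config.misassignment_rate, len(starts))
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts,
            "end": np.minimum(starts + w, config.chromosome_length),
            "d1": np.where(is1, d_true, d_other).astype(float),
            "d2": np.where(is1, d_other, d_true).astype(float),
        }))
    return pd.concat(frames, ignore_index=True)


def _simulate_srna(config, sites, gain_mask, rng):
    """Background sRNA clusters plus trans clusters at opposite-origin gains.

    The parent-1 track overlaps a configured fraction of gain sites lying in
    parent-2-derived segments (and vice versa), reproducing qualitatively the
    trans small-RNA association at methylation-gain sites.
    """
    tracks = {}
    for track_parent, opposite in (("hom1", "hom2"), ("hom2", "hom1")):
        rows = []
        for chrom in sorted(sites["chrom"].unique()):
            n_bg = rng.poisson(config.srna_cluster_rate
                               * config.chromosome_length / 1e6)
            starts = rng.integers(0, config.chromosome_length - 300,
                                  size=max(n_bg, 0))
            for s in starts:
                rows.append((chrom, int(s), int(s) + int(rng.integers(50, 300)),
                             1.0 + rng.exponential(1.0)))
        target = gain_mask & (sites["origin"] == opposite).to_numpy()
        hits = sites[target & (rng.random(len(sites))
                               < config.srna_gain_overlap_frac)]
        for r in hits.itertuples():
            rows.append((r.chrom, max(r.pos - 12, 0), r.pos + 14,
                         1.0 + rng.exponential(1.0)))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        tracks[track_parent] = df.sort_values(
            ["chrom", "start"]).reset_index(drop=True)
    return tracks["hom1"], tracks["hom2"]


# ---------------------------------------------------------------------------
# strain panel


_PANEL_ARCHETYPES = {
    # each archetype: (component base levels, component weights)
    "invariant_low": ([LOW_LEVEL], [1.0]),
    "invariant_high": ([0.95], [1.0]),
    "bimodal_low": ([LOW_LEVEL, 0.95], [0.9, 0.1]),
    "bimodal_high": ([LOW_LEVEL, 0.95], [0.1, 0.9]),
    "bimodal_med": ([LOW_LEVEL, 0.95], [0.5, 0.5]),
    # a flat histogram collapses to a single plateau peak under the peak
    # rule, so the distributed class is generated as a trimodal mixture
    "distributed": ([0.1, 0.5, 0.9], [0.35, 0.3, 0.35]),
}


def simulate_strain_panel(config: SimulationConfig,
                          sites: pd.DataFrame | None = None,
                          class_probs: Sequence[float] | None = None,
                          ) -> SimulatedPanel:
    """Sites-by-strains methylation matrix drawn from class archetypes."""
    if config.n_strains_panel < 10:
        raise ConfigurationError("n_strains_panel must be >= 10")
    rng = np.random.default_rng([config.seed, 3])
    n_sites = len(sites) if sites is not None else config.n_panel_sites
    n_strains = config.n_strains_panel
    probs = (np.asarray(class_probs, dtype=float) if class_probs is not None
             else np.full(6, 1 / 6))
    classes = rng.choice(BINS6, size=n_sites, p=probs / probs.sum())

    levels = np.empty((n_sites, n_strains))
    for name, (bases, weights) in _PANEL_ARCHETYPES.items():
        m = classes == name
        if not m.any():
            continue
        comp = rng.choice(len(bases), size=(m.sum(), n_strains),
                          p=np.asarray(weights) / np.sum(weights))
        base = np.asarray(bases)[comp]
        levels[m] = np.clip(
            base + rng.normal(0, config.panel_noise_sd, base.shape), 0, 1)

    coverage = rng.poisson(config.depth_mean, size=(n_sites, n_strains))
    low = rng.random((n_sites, n_strains)) < config.panel_missing_frac
    coverage = np.where(low, rng.poisson(1.5, size=coverage.shape), coverage)

    if sites is not None:
        index = [f"{c}:{p}" for c, p in zip(sites["chrom"], sites["pos"])]
        site_df = sites[["chrom", "pos"]].reset_index(drop=True)
    else:
        index = [f"site{i:05d}" for i in range(n_sites)]
        site_df = pd.DataFrame({"site": index})
    strains = [f"strain{j:03d}" for j in range(n_strains)]
    return SimulatedPanel(
        levels=pd.DataFrame(levels, index=index, columns=strains),
        coverage=pd.DataFrame(coverage, index=index, columns=strains),
        truth=pd.Series(classes, index=index, name="class6"),
        sites=site_df,
    )


# ---------------------------------------------------------------------------
# helpers for scaled experiments


def simulate_count_table(levels: np.ndarray, depth_mean: float, rng,
                         chrom: str = "chr1",
                         spacing: int = 50) -> pd.DataFrame:
    """Merged-CG-style count table directly from a vector of true levels."""
    n = len(levels)
    depth = rng.poisson(depth_mean, size=n)
    n_meth = rng.binomial(depth, levels)
    pos = np.arange(n, dtype=np.int64) * spacing
    with np.errstate(invalid="ignore"):
        lvl = np.where(depth > 0, n_meth / np.maximum(depth, 1), np.nan)
    return pd.DataFrame({"chrom": chrom, "pos": pos, "n_meth": n_meth,
                         "n_unmeth": depth - n_meth, "level": lvl})


def simulate_genome_sequence(parents: SimulatedParents,
                             rng=None) -> dict[str, str]:
    """Random genome with a CG dinucleotide forced at every CG site."""
    config = parents.config
    rng = rng or np.random.default_rng([config.seed, 4])
    genome = {}
    bases = np.array(list("ACGT"))
    for chrom in _chrom_names(config):
        seq = bases[rng.integers(0, 4, size=config.chromosome_length)]
        cg = parents.sites.query("chrom == @chrom and context == 'CG'")
        pos = cg["pos"].to_numpy()
        seq[pos] = "C"
        seq[pos + 1] = "G"
        genome[chrom] = "".join(seq)
    return genome
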