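"""Genomic clustering of outlier genes: permutation tests, sliding-window
scans for outlying regions, and subtelomere enrichment.

Two clustering statistics are tested against a permutation null in which
the observed number of outliers is reassigned to random genes of the
analyzed universe:

* the mean genomic distance (midpoint to midpoint) between consecutive
  outliers on the same chromosome — small under clustering (left tail);
* the number of outlier genes inside "islands", maximal runs of two or
  more genes that are consecutive in the universe's gene order along a
  chromosome and all flagged — large under clustering (right tail).

Monte-Carlo p-values use the (k+1)/(N+1) estimator; when the number of
distinct placements C(n, k) is small the null is enumerated exhaustively
and the p-value is exact.  Because the island count is a small integer,
its Monte-Carlo p-value is also returned in a tie-randomized form
(uniform on the null) for calibration diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenomeLayout",
    "PermutationResult",
    "Region",
    "permutation_clustering",
    "sliding_window_scan",
    "subtelomere_enrichment",
    "genetic_map_subtelomeres",
]


@dataclass
class GenomeLayout:
    """Gene coordinates (0-based half-open, bp) plus chromosome lengths
    and an optional genetic map (gene, linkage_group, cM)."""

    genes: pd.DataFrame                 # gene, chromosome, start, end
    chromosome_lengths: dict[str, int]
    genetic_map: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        required = {"gene", "chromosome", "start", "end"}
        missing = required - set(self.genes.columns)
        if missing:
            raise ValueError(f"layout missing columns: {sorted(missing)}")
        if self.genes.gene.duplicated().any():
            raise ValueError("duplicate gene ids in layout")
        for r in self.genes.itertuples(index=False):
            limit = self.chromosome_lengths.get(r.chromosome)
            if limit is not None and (r.start < 0 or r.end > limit):
                raise ValueError(f"{r.gene} outside {r.chromosome} bounds")

    def midpoints(self) -> pd.DataFrame:
        df = self.genes.copy()
        df["midpoint"] = (df.start + df.end) / 2.0
        return df

    @classmethod
    def from_bed(cls, bed_path, chrom_path=None, map_path=None) -> "GenomeLayout":
        genes = pd.read_csv(
            bed_path, sep="\t", header=None,
            names=["chromosome", "start", "end", "gene"],
        )[["gene", "chromosome", "start", "end"]]
        lengths = {}
        if chrom_path is not None:
            ct = pd.read_csv(chrom_path, sep="\t")
            lengths = dict(zip(ct.chromosome, ct.length))
        else:
            lengths = genes.groupby("chromosome").end.max().to_dict()
        gmap = pd.read_csv(map_path, sep="\t") if map_path is not None else None
        return cls(genes=genes, chromosome_lengths=lengths, genetic_map=gmap)


@dataclass
class PermutationResult:
    statistic: str
    observed: float
    n_permutations: int
    exceedances: int
    p_value: float
    exact: bool
    p_randomized: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError("permutation p-value must lie in (0, 1]")


@dataclass
class Region:
    chromosome: str
    start: float
    end: float
    n_windows: int
    n_genes: int
    mean_value: float


def _ordered_universe(layout: GenomeLayout, universe: list[str]):
    """Universe genes sorted by (chromosome, midpoint); returns midpoints,
    chromosome codes, and the position of each gene in the order."""
    df = layout.midpoints()
    df = df[df.gene.isin(universe)].sort_values(
        ["chromosome", "midpoint"], kind="mergesort"
    )
    mid = df.midpoint.values
    chrom = pd.factorize(df.chromosome)[0]
    pos = {g: i for i, g in enumerate(df.gene)}
    return df.gene.values, mid, chrom, pos


def _cluster_stats(flag_rows: np.ndarray, mid: np.ndarray, chrom: np.ndarray):
    """Vectorized clustering statistics for many permutations at once.

    flag_rows: (nrep, n) boolean outlier indicators in universe order.
    Returns (mean consecutive distance, island gene count) per row; the
    distance is NaN for rows with < 2 outliers on every chromosome.
    """
    flag_rows = np.atleast_2d(flag_rows)
    nrep, n = flag_rows.shape
    same_chrom = chrom[1:] == chrom[:-1]

    # island count: flagged genes adjacent in universe order
    adj = flag_rows[:, 1:] & flag_rows[:, :-1] & same_chrom
    # count genes in runs >= 2: every adjacency contributes its two ends,
    # shared ends counted once -> genes_in_islands = flagged genes that
    # touch at least one adjacency
    touch = np.zeros_like(flag_rows)
    touch[:, 1:] |= adj
    touch[:, :-1] |= adj
    island_genes = touch.sum(axis=1).astype(float)

    mean_dist = np.full(nrep, np.nan)
    for r in range(nrep):
        idx = np.nonzero(flag_rows[r])[0]
        if idx.size < 2:
            continue
        ok = chrom[idx[1:]] == chrom[idx[:-1]]
        if ok.any():
            d = mid[idx[1:]][ok] - mid[idx[:-1]][ok]
            mean_dist[r] = d.mean()
    return mean_dist, island_genes


def permutation_clustering(
    layout: GenomeLayout,
    outliers: set[str],
    universe: list[str],
    n_permutations: int = 10_000,
    seed: int | None = None,
    exhaustive_limit: int = 100_000,
) -> dict[str, PermutationResult]:
    """Test whether outlier genes cluster in the genome.

    The null reassigns |outliers| flags to random genes of the universe
    without replacement.  Exhaustive enumeration replaces Monte Carlo
    when C(n, k) <= ``exhaustive_limit``.  Left-tail p for the mean
    inter-outlier distance, right-tail for the island gene count.
    """
    if not set(outliers) <= set(universe):
        raise ValueError("outlier set must be a subset of the universe")
    genes, mid, chrom, pos = _ordered_universe(layout, universe)
    n = len(genes)
    k = len(outliers)
    unmapped = set(universe) - set(genes)
    if unmapped:
        raise ValueError(f"universe genes missing from layout: {sorted(unmapped)[:5]}")

    obs_flags = np.zeros(n, dtype=bool)
    for g in outliers:
        obs_flags[pos[g]] = True
    obs_dist, obs_isl = _cluster_stats(obs_flags, mid, chrom)
    obs_dist, obs_isl = float(obs_dist[0]), float(obs_isl[0])

    results: dict[str, PermutationResult] = {}
    if k == n or k == 0:
        # degenerate: only one possible placement
        for name, obs in (("mean_distance", obs_dist), ("island_genes", obs_isl)):
            results[name] = PermutationResult(name, obs, 0, 0, 1.0, True, 1.0)
        return results

    exhaustive = comb(n, k) <= exhaustive_limit
    if exhaustive:
        placements = list(combinations(range(n), k))
        flags = np.zeros((len(placements), n), dtype=bool)
        for i, c in enumerate(placements):
            flags[i, list(c)] = True
        dist, isl = _cluster_stats(flags, mid, chrom)
        n_eff = len(placements)
        if np.isnan(obs_dist):
            results["mean_distance"] = PermutationResult(
                "mean_distance", obs_dist, n_eff, 0, 1.0, True, None)
        else:
            k_le = int(np.sum(dist[~np.isnan(dist)] <= obs_dist))
            results["mean_distance"] = PermutationResult(
                "mean_distance", obs_dist, n_eff, k_le, k_le / n_eff, True, None)
        k_ge = int(np.sum(isl >= obs_isl))
        results["island_genes"] = PermutationResult(
            "island_genes", obs_isl, n_eff, k_ge, k_ge / n_eff, True,
            None)
        return results

    rng = np.random.default_rng(seed)
    nrep = n_permutations
    # sample k-subsets via argpartition of random keys (chunked)
    chunk = max(1, min(nrep, int(2e7 // max(n, 1))))
    dists = np.empty(nrep)
    isls = np.empty(nrep)
    done = 0
    while done < nrep:
        m = min(chunk, nrep - done)
        keys = rng.random((m, n))
        idx = np.argpartition(keys, k, axis=1)[:, :k]
        flags = np.zeros((m, n), dtype=bool)
        np.put_along_axis(flags, idx, True, axis=1)
        d, s = _cluster_stats(flags, mid, chrom)
        dists[done : done + m] = d
        isls[done : done + m] = s
        done += m

    u = rng.random(2)
    if np.isnan(obs_dist):
        results["mean_distance"] = PermutationResult(
            "mean_distance", obs_dist, nrep, 0, 1.0, False, None)
    else:
        valid = ~np.isnan(dists)
        k_le = int(np.sum(dists[valid] <= obs_dist))
        p = (k_le + 1) / (nrep + 1)
        results["mean_distance"] = PermutationResult(
            "mean_distance", obs_dist, nrep, k_le, p, False, None)
    k_ge = int(np.sum(isls >= obs_isl))
    k_gt = int(np.sum(isls > obs_isl))
    p = (k_ge + 1) / (nrep + 1)
    # tie-randomized p-value: exactly uniform under the null, used for
    # calibration diagnostics on discrete statistics
    p_rand = (k_gt + u[1] * (k_ge - k_gt + 1)) / (nrep + 1)
    results["island_genes"] = PermutationResult(
        "island_genes", obs_isl, nrep, k_ge, p, False, float(p_rand))
    return results


def sliding_window_scan(
    layout: GenomeLayout,
    values: pd.Series,
    window_mb: float = 1.0,
    step_mb: float = 0.25,
    min_genes: int = 4,
    threshold: float = 2.5,
    statistic: str = "mean",
) -> list[Region]:
    """Scan for outlying regions: windows tile each chromosome from zero;
    a gene belongs to a window when its midpoint lies in [start, end);
    windows with at least ``min_genes`` genes and window statistic
    (mean by default, optionally median) strictly above ``threshold``
    qualify; overlapping or abutting qualifying windows are collapsed
    into regions.

    ``values`` is indexed by gene id (typically normalized dS_WS).
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    window = window_mb * 1e6
    step = step_mb * 1e6
    df = layout.midpoints()
    df = df[df.gene.isin(values.index)]
    df = df.assign(value=values.reindex(df.gene).values)
    df = df[np.isfinite(df.value)]

    qualifying: list[tuple[str, float, float, float]] = []
    for chrom, sub in df.groupby("chromosome"):
        length = layout.chromosome_lengths.get(chrom, float(sub.midpoint.max()))
        mids = sub.midpoint.values
        vals = sub.value.values
        start = 0.0
        while start < length:
            end = start + window
            inside = (mids >= start) & (mids < end)
            if inside.sum() >= min_genes:
                stat = (np.mean(vals[inside]) if statistic == "mean"
                        else np.median(vals[inside]))
                if stat > threshold:
                    qualifying.append((chrom, start, min(end, length), stat))
            start += step

    regions: list[Region] = []
    by_chrom: dict[str, list] = {}
    for q in qualifying:
        by_chrom.setdefault(q[0], []).append(q)
    for chrom in sorted(by_chrom):
        wins = sorted(by_chrom[chrom], key=lambda w: w[1])
        cur = [wins[0]]
        for w in wins[1:]:
            if w[1] <= cur[-1][2]:        # overlap or abut
                cur.append(w)
            else:
                regions.append(_collapse(chrom, cur, df))
                cur = [w]
        regions.append(_collapse(chrom, cur, df))
    return regions


def _collapse(chrom: str, windows: list, df: pd.DataFrame) -> Region:
    start = min(w[1] for w in windows)
    end = max(w[2] for w in windows)
    sub = df[(df.chromosome == chrom) & (df.midpoint >= start) & (df.midpoint < end)]
    return Region(
        chromosome=chrom,
        start=start,
        end=end,
        n_windows=len(windows),
        n_genes=len(sub),
        mean_value=float(sub.value.mean()) if len(sub) else float("nan"),
    )


def subtelomere_enrichment(
    layout: GenomeLayout,
    outliers: set[str],
    universe: list[str],
    margin_mb: float = 5.0,
) -> dict:
    """2x2 chi-squared test of outlier status vs subtelomeric location.

    A gene is subtelomeric when its midpoint lies within ``margin_mb`` of
    either end of its chromosome.  Chromosomes shorter than twice the
    margin are wholly subtelomeric and reported in ``warnings``.
    """
    margin = margin_mb * 1e6
    df = layout.midpoints()
    df = df[df.gene.isin(universe)]
    warnings = []
    flags = {}
    for r in df.itertuples(index=False):
        length = layout.chromosome_lengths[r.chromosome]
        if length < 2 * margin and r.chromosome not in warnings:
            warnings.append(r.chromosome)
        flags[r.gene] = r.midpoint < margin or r.midpoint > length - margin
    sub = np.array([flags[g] for g in df.gene])
    out = np.array([g in outliers for g in df.gene])
    table = np.array(
        [
            [(out & sub).sum(), (out & ~sub).sum()],
            [(~out & sub).sum(), (~out & ~sub).sum()],
        ]
    )
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        chi2, p = np.nan, np.nan
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {
        "table": table,
        "chi2": float(chi2) if np.isfinite(chi2) else np.nan,
        "p_value": float(p) if np.isfinite(p) else np.nan,
        "subtelomeric_flags": flags,
        "warnings": warnings,
    }


def genetic_map_subtelomeres(
    genetic_map: pd.DataFrame,
    universe: list[str] | None = None,
    margin_cm: float | None = None,
    physical_margin_mb: float = 5.0,
    rate_cm_per_mb: float = 0.57,
) -> dict:
    """Flag genes within ``margin_cm`` of either end of their linkage
    group's span on a genetic map.

    When ``margin_cm`` is not given it is derived from the physical
    margin and the genome-average recombination rate:
    5 Mb x 0.57 cM/Mb = 2.85 cM.  Genes absent from the map are reported
    separately as unmapped.
    """
    if margin_cm is None:
        margin_cm = physical_margin_mb * rate_cm_per_mb
    gm = genetic_map
    if universe is not None:
        mapped_ids = set(gm.gene)
        unmapped = [g for g in universe if g not in mapped_ids]
        gm = gm[gm.gene.isin(universe)]
    else:
        unmapped = []
    flags = {}
    for lg, sub in gm.groupby("linkage_group"):
        lo, hi = sub.cM.min(), sub.cM.max()
        for r in sub.itertuples(index=False):
            flags[r.gene] = (r.cM - lo <= margin_cm) or (hi - r.cM <= margin_cm)
    return {
        "margin_cm": float(margin_cm),
        "subtelomeric_flags": flags,
        "unmapped": unmapped,
    }
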