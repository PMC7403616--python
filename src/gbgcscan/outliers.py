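"""Alignment filtering, per-species rate normalization, and outlier calling.

The normalization follows the lineage-control logic of the analysis: each
raw rate is divided by the mean rate of its species x mutational category
over all genes with a finite value, so that species with different
average evolutionary rates become comparable; a gene is an outlier in a
category when its normalized rate strictly exceeds 2.5.

Alignment filters mirror the upstream quality rules applied to the
orthogroup alignments: alignments whose longest ungapped sequence is
shorter than 400 bp are dropped, sequences whose gap count exceeds 40%
of the non-gap length of the longest sequence are masked, and alignments
where more than two non-protected species are masked or missing are
dropped entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import codons as cd

__all__ = [
    "FilterReport",
    "filter_alignments",
    "normalize_and_flag",
    "outlier_overlap",
    "compare_groups",
    "chimney_fraction",
    "outlier_category_tests",
    "gc3_species_tests",
    "dunn_posthoc",
]

#: Species that must never be masked or missing for an alignment to be
#: retained (outgroup plus the four focal species).
PROTECTED_SPECIES = (
    "Homo_sapiens",
    "Mus_musculus",
    "Rattus_norvegicus",
    "Psammomys_obesus",
    "Meriones_unguiculatus",
)

RATE_COLUMNS = list(cd.CATEGORY_LABELS)


@dataclass
class FilterReport:
    """Accounting of every filter action, for reproducible bookkeeping."""

    dropped_short: list[str] = field(default_factory=list)
    masked: dict[str, list[str]] = field(default_factory=dict)
    dropped_missing: list[str] = field(default_factory=list)


def _ungapped_length(seq: str) -> int:
    return len(seq) - seq.count("-")


def filter_alignments(
    alignments: dict[str, dict[str, str]],
    *,
    min_longest_bp: int = 400,
    max_gap_fraction: float = 0.40,
    max_masked_or_missing: int = 2,
    protected: tuple[str, ...] = PROTECTED_SPECIES,
    roster: tuple[str, ...] | None = None,
) -> tuple[dict[str, dict[str, str]], FilterReport]:
    """Apply the alignment quality filters, in order.

    1. Drop the alignment if its longest ungapped sequence is < 400 bp.
    2. Mask (remove) any sequence whose gap count exceeds 40% of the
       non-gap length of the longest sequence.
    3. Drop the alignment if more than two non-protected species are
       masked or missing relative to ``roster`` (default: the union of
       species seen across alignments); any masked/missing protected
       species also drops the alignment.

    Returns the retained alignments and a report listing every action.
    """
    report = FilterReport()
    if roster is None:
        seen: set[str] = set()
        for aln in alignments.values():
            seen.update(aln)
        roster = tuple(sorted(seen))
    retained: dict[str, dict[str, str]] = {}
    for gid in sorted(alignments):
        aln = alignments[gid]
        if not aln:
            report.dropped_short.append(gid)
            continue
        longest = max(_ungapped_length(s) for s in aln.values())
        if longest < min_longest_bp:
            report.dropped_short.append(gid)
            continue
        gap_limit = max_gap_fraction * longest
        kept = {}
        masked_here = []
        for sp, seq in aln.items():
            if seq.count("-") > gap_limit:
                masked_here.append(sp)
            else:
                kept[sp] = seq
        if masked_here:
            report.masked[gid] = sorted(masked_here)
        absent = [sp for sp in roster if sp not in kept]
        n_bad = sum(1 for sp in absent if sp not in protected)
        protected_bad = [sp for sp in absent if sp in protected]
        if n_bad > max_masked_or_missing or protected_bad:
            report.dropped_missing.append(gid)
            continue
        retained[gid] = kept
    return retained, report


def normalize_and_flag(
    rates: pd.DataFrame,
    threshold: float = 2.5,
    rate_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Normalize rates per species x category and flag outliers.

    For every rate column the per-species mean over genes with finite
    values is computed; ``norm_<col>`` is the raw value divided by that
    mean, and ``out_<col>`` flags genes whose normalized rate is strictly
    greater than ``threshold``.  A species x category whose mean is zero
    is degenerate: its normalized values are NaN and recorded in
    ``attrs['degenerate']``.
    """
    rate_columns = rate_columns or RATE_COLUMNS
    df = rates.copy()
    degenerate = []
    for col in rate_columns:
        means = df.groupby("species")[col].transform("mean")
        zero = means == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            df[f"norm_{col}"] = np.where(zero, np.nan, df[col] / means)
        df[f"out_{col}"] = df[f"norm_{col}"] > threshold
        for sp in df.loc[zero, "species"].unique():
            degenerate.append((sp, col))
    df.attrs["degenerate"] = degenerate
    df.attrs["threshold"] = threshold
    return df


def outlier_overlap(flags: dict[str, set[str]]) -> dict:
    """Set algebra over per-species outlier gene sets: per-species counts,
    all pairwise intersections, the joint intersection, and the union."""
    species = sorted(flags)
    pairwise = {
        (a, b): flags[a] & flags[b]
        for i, a in enumerate(species)
        for b in species[i + 1 :]
    }
    joint = set.intersection(*flags.values()) if flags else set()
    union = set.union(*flags.values()) if flags else set()
    return {
        "per_species": {sp: len(flags[sp]) for sp in species},
        "pairwise": {k: len(v) for k, v in pairwise.items()},
        "pairwise_sets": pairwise,
        "intersection": joint,
        "union": union,
    }


def compare_groups(
    values: pd.Series | np.ndarray,
    in_group: pd.Series | np.ndarray,
    alternative: str = "greater",
) -> dict:
    """One-tailed Wilcoxon rank-sum comparison of group vs rest.

    ``alternative='greater'`` tests whether the flagged group tends to
    have larger values.  Degenerate groups (either side empty) are
    reported with NaN statistics.
    """
    values = np.asarray(values, dtype=float)
    in_group = np.asarray(in_group, dtype=bool)
    ok = np.isfinite(values)
    a = values[ok & in_group]
    b = values[ok & ~in_group]
    if len(a) == 0 or len(b) == 0:
        return {"statistic": np.nan, "p_value": np.nan, "n_group": len(a),
                "n_rest": len(b), "degenerate": True}
    stat, p = stats.mannwhitneyu(a, b, alternative=alternative)
    return {"statistic": float(stat), "p_value": float(p), "n_group": len(a),
            "n_rest": len(b), "degenerate": False}


def flag_cooccurrence(
    flags_a: pd.Series | np.ndarray, flags_b: pd.Series | np.ndarray
) -> dict:
    """Chi-squared and Fisher tests of co-occurrence of two outlier flags
    on the same gene universe."""
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    table = np.array(
        [[(a & b).sum(), (a & ~b).sum()], [(~a & b).sum(), (~a & ~b).sum()]]
    )
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        return {"table": table, "chi2": np.nan, "p_chi2": np.nan,
                "p_fisher": np.nan, "degenerate": True}
    chi2, p_chi2, _, _ = stats.chi2_contingency(table, correction=False)
    _, p_fisher = stats.fisher_exact(table)
    return {"table": table, "chi2": float(chi2), "p_chi2": float(p_chi2),
            "p_fisher": float(p_fisher), "degenerate": False}


def chimney_fraction(table: pd.DataFrame, species: str) -> float:
    """Fraction of a species' dS_WS outliers whose dS_WS exceeds dS_SW —
    the signature of GC-skewed (rather than merely fast) evolution."""
    sub = table[(table.species == species) & table.out_dS_WS]
    if len(sub) == 0:
        return float("nan")
    return float((sub.dS_WS > sub.dS_SW).mean())


def outlier_category_tests(
    table: pd.DataFrame,
    species: str,
    categories: tuple[str, ...] = ("dS_SW", "dS_WW", "dS_SS",
                                   "dN_WS", "dN_SW", "dN_WW", "dN_SS"),
) -> pd.DataFrame:
    """For one species: do dS_WS outliers have elevated rates in the other
    categories?  One-tailed rank-sum per category, plus chi-squared
    co-occurrence of the outlier flags."""
    sub = table[table.species == species]
    rows = []
    for col in categories:
        rs = compare_groups(sub[f"norm_{col}"], sub.out_dS_WS, "greater")
        co = flag_cooccurrence(sub.out_dS_WS, sub[f"out_{col}"])
        rows.append(
            {
                "category": col,
                "ranksum_p": rs["p_value"],
                "median_out": sub.loc[sub.out_dS_WS, f"norm_{col}"].median(),
                "median_rest": sub.loc[~sub.out_dS_WS, f"norm_{col}"].median(),
                "cooccur_chi2": co["chi2"],
                "cooccur_p": co["p_chi2"],
            }
        )
    return pd.DataFrame(rows)


def dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise z-tests on joint ranks after a Kruskal-Wallis
    test, with Benjamini-Hochberg correction across the pairs."""
    names = sorted(groups)
    pooled = np.concatenate([np.asarray(groups[g], float) for g in names])
    labels = np.concatenate(
        [np.full(len(groups[g]), i) for i, g in enumerate(names)]
    )
    ok = np.isfinite(pooled)
    pooled, labels = pooled[ok], labels[ok]
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    rows = []
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            ra = ranks[labels == i].mean()
            rb = ranks[labels == j].mean()
            na = (labels == i).sum()
            nb = (labels == j).sum()
            se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
            z = (ra - rb) / se
            p = 2 * stats.norm.sf(abs(z))
            rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_bh"] = multipletests(df.p_raw.values, method="fdr_bh")[1]
    return df


def gc3_species_tests(table: pd.DataFrame) -> dict:
    """Kruskal-Wallis comparison of GC3 distributions across the focal
    species, with Dunn/Benjamini-Hochberg pairwise follow-up."""
    groups = {
        sp: table.loc[table.species == sp, "gc3"].dropna().values
        for sp in table.species.unique()
    }
    groups = {sp: v for sp, v in groups.items() if len(v) > 0}
    if len(groups) < 2:
        return {"kruskal_h": np.nan, "kruskal_p": np.nan, "dunn": None,
                "degenerate": True}
    h, p = stats.kruskal(*groups.values())
    return {
        "kruskal_h": float(h),
        "kruskal_p": float(p),
        "dunn": dunn_posthoc(groups),
        "degenerate": False,
    }


def gerbil_outlier_sets(table: pd.DataFrame, category: str = "dS_WS") -> dict[str, set[str]]:
    """Per-species outlier gene sets for one category."""
    col = f"out_{category}"
    return {
        sp: set(table.loc[(table.species == sp) & table[col], "gene"])
        for sp in table.species.unique()
    }
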