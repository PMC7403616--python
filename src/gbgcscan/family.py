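"""GC3 ranking of focal-species genes within their wider gene families.

A gene under sustained GC-skewed substitution is expected not only to
exceed its rodent orthologs in GC3 but to climb toward the top of its
whole gene family (orthologs plus paralogs across distant taxa).  Each
focal-species sequence is ranked against the family's comparator
sequences: rank 1 means the highest GC3 in the family.  Ties are broken
pessimistically (a tied comparator counts as greater), which makes the
"top three" classification conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import codons as cd
from .outliers import compare_groups

__all__ = ["FamilyRankRecord", "rank_in_family", "rank_families", "rank_enrichment"]


@dataclass(frozen=True)
class FamilyRankRecord:
    family: str
    species: str
    gene: str
    focal_gc3: float
    family_size: int          # number of comparator sequences
    rank: int                 # 1 = highest GC3
    top3: bool

    def __post_init__(self):
        if not (1 <= self.rank <= self.family_size + 1):
            raise ValueError("rank out of range")
        if self.top3 != (self.rank <= 3):
            raise ValueError("top3 flag inconsistent with rank")


def rank_in_family(
    family: str,
    species: str,
    gene: str,
    focal_gc3: float,
    comparator_gc3: list[float],
    excluded_species: tuple[str, ...] = (),
    comparator_species: list[str] | None = None,
) -> FamilyRankRecord:
    """Rank a focal GC3 value against family comparators.

    rank = 1 + number of comparators with GC3 >= focal (pessimistic tie
    rule).  Comparators from ``excluded_species`` are removed first (to
    avoid double-counting species already represented by the focal set).
    Raises ValueError if no comparator remains.
    """
    vals = list(comparator_gc3)
    if comparator_species is not None:
        vals = [
            v
            for v, sp in zip(vals, comparator_species)
            if sp not in excluded_species
        ]
    vals = [v for v in vals if np.isfinite(v)]
    if not vals:
        raise ValueError(f"family {family}: no comparator sequences remain")
    rank = 1 + sum(1 for v in vals if v >= focal_gc3)
    return FamilyRankRecord(
        family=family,
        species=species,
        gene=gene,
        focal_gc3=float(focal_gc3),
        family_size=len(vals),
        rank=rank,
        top3=rank <= 3,
    )


def rank_families(
    families: pd.DataFrame,
    family_sequences: dict[str, dict[str, str]],
    focal_gc3: pd.DataFrame,
    excluded_species: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Build family-rank records for every (gene, focal species).

    ``families`` maps family -> gene; ``family_sequences`` holds the
    comparator sequences per family; ``focal_gc3`` is a long table with
    columns gene, species, gc3.  Comparator sequences whose length is
    not a multiple of three are excluded (same rule as the main GC
    statistics); families left without comparators are skipped and
    listed in ``attrs['skipped']``.
    """
    rows = []
    skipped = []
    fam_by_gene = dict(zip(families.gene, families.family))
    for (gene, species), sub in focal_gc3.groupby(["gene", "species"]):
        fam = fam_by_gene.get(gene)
        if fam is None or fam not in family_sequences:
            skipped.append((gene, species, "no family"))
            continue
        gc3 = sub.gc3.iloc[0]
        if not np.isfinite(gc3):
            skipped.append((gene, species, "no focal GC3"))
            continue
        comp = []
        for sid, seq in sorted(family_sequences[fam].items()):
            try:
                comp.append(cd.gc_content(seq.replace("-", "")).gc3)
            except cd.CodonError:
                continue
        try:
            rec = rank_in_family(fam, species, gene, gc3, comp,
                                 excluded_species)
        except ValueError:
            skipped.append((gene, species, "no comparators"))
            continue
        rows.append(rec.__dict__)
    df = pd.DataFrame(rows)
    df.attrs["skipped"] = skipped
    return df


def rank_enrichment(records: pd.DataFrame, outlier_flags: pd.DataFrame) -> dict:
    """Tests of high-GC3-rank enrichment.

    * per-species top-3 counts and proportions;
    * chi-squared test of top-3 proportion across species;
    * per-species one-tailed rank-sum: do dS_WS outliers have better
      (smaller) family ranks than non-outliers?
    * per-species 2x2 test of top-3 x outlier membership, plus a
      cross-species comparison of the outlier share among top-3 genes.

    ``outlier_flags`` is a long table with columns gene, species,
    out_dS_WS.
    """
    merged = records.merge(outlier_flags, on=["gene", "species"], how="left")
    merged["out_dS_WS"] = merged.out_dS_WS.fillna(False).astype(bool)
    species = sorted(merged.species.unique())
    if len(species) < 2:
        raise ValueError("need at least two species with records")

    top3_table = np.array(
        [
            [
                int(merged[(merged.species == sp) & merged.top3].shape[0]),
                int(merged[(merged.species == sp) & ~merged.top3].shape[0]),
            ]
            for sp in species
        ]
    )
    if top3_table.min() >= 0 and top3_table.sum(axis=1).min() > 0:
        chi2, chi2_p, _, _ = stats.chi2_contingency(top3_table)
    else:
        chi2, chi2_p = np.nan, np.nan

    per_species = {}
    outlier_in_top3 = []
    for i, sp in enumerate(species):
        sub = merged[merged.species == sp]
        # outliers should have smaller rank numbers -> test "less"
        rs = compare_groups(sub["rank"], sub.out_dS_WS, alternative="less")
        tab = np.array(
            [
                [int((sub.top3 & sub.out_dS_WS).sum()),
                 int((sub.top3 & ~sub.out_dS_WS).sum())],
                [int((~sub.top3 & sub.out_dS_WS).sum()),
                 int((~sub.top3 & ~sub.out_dS_WS).sum())],
            ]
        )
        if tab.sum(axis=1).min() > 0 and tab.sum(axis=0).min() > 0:
            _, fisher_p = stats.fisher_exact(tab)
        else:
            fisher_p = np.nan
        per_species[sp] = {
            "n": int(len(sub)),
            "top3": int(top3_table[i, 0]),
            "top3_fraction": float(top3_table[i, 0] / max(len(sub), 1)),
            "ranksum_p": rs["p_value"],
            "top3_outlier_table": tab,
            "top3_outlier_fisher_p": float(fisher_p)
            if np.isfinite(fisher_p) else np.nan,
        }
        outlier_in_top3.append(
            [int((sub.top3 & sub.out_dS_WS).sum()),
             int((sub.top3 & ~sub.out_dS_WS).sum())]
        )
    cross = np.array(outlier_in_top3)
    if cross.sum(axis=1).min() > 0 and cross.sum(axis=0).min() > 0:
        cross_chi2, cross_p, _, _ = stats.chi2_contingency(cross)
    else:
        cross_chi2, cross_p = np.nan, np.nan
    return {
        "species": species,
        "top3_table": top3_table,
        "top3_chi2": float(chi2) if np.isfinite(chi2) else np.nan,
        "top3_chi2_p": float(chi2_p) if np.isfinite(chi2_p) else np.nan,
        "per_species": per_species,
        "top3_outlier_cross_chi2": float(cross_chi2)
        if np.isfinite(cross_chi2) else np.nan,
        "top3_outlier_cross_p": float(cross_p)
        if np.isfinite(cross_p) else np.nan,
    }
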