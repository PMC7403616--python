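"""Alignment filters, normalization/flagging, overlap algebra, and the
statistical comparisons between outlier and non-outlier genes."""

import numpy as np
import pandas as pd
import pytest

from gbgcscan import outliers as out


def _aln(**seqs):
    return dict(seqs)


class TestFilterAlignments:
    def test_short_alignment_dropped_at_boundary(self):
        roster = ("s1", "s2")
        short = {"g": _aln(s1="A" * 399, s2="A" * 399)}
        kept, rep = out.filter_alignments(short, roster=roster, protected=())
        assert kept == {} and rep.dropped_short == ["g"]
        ok = {"g": _aln(s1="A" * 400, s2="A" * 400)}
        kept, rep = out.filter_alignments(ok, roster=roster, protected=())
        assert "g" in kept

    def test_gap_fraction_masking_boundary(self):
        # longest non-gap length 1000; the 40% limit is 400 gaps:
        # exactly 400 gaps is kept, 401 is masked
        longest = "A" * 1000
        at_limit = "A" * 600 + "-" * 400
        over_limit = "A" * 599 + "-" * 401
        aln = {"g": _aln(s1=longest, s2=at_limit, s3=over_limit)}
        kept, rep = out.filter_alignments(
            aln, roster=("s1", "s2", "s3"), protected=(),
            max_masked_or_missing=2,
        )
        assert set(kept["g"]) == {"s1", "s2"}
        assert rep.masked["g"] == ["s3"]

    def test_three_masked_nonprotected_species_drop_alignment(self):
        longest = "A" * 1000
        bad = "A" * 500 + "-" * 500
        aln = {"g": _aln(p1=longest, s1=bad, s2=bad, s3=bad)}
        kept, rep = out.filter_alignments(
            aln, roster=("p1", "s1", "s2", "s3"), protected=("p1",),
        )
        assert kept == {} and rep.dropped_missing == ["g"]

    def test_masked_protected_species_drops_alignment(self):
        longest = "A" * 1000
        aln = {"g": _aln(s1=longest, Mus_musculus="A" * 100 + "-" * 900)}
        kept, _ = out.filter_alignments(
            aln, roster=("s1", "Mus_musculus"),
        )
        assert kept == {}


def _rate_frame():
    # two species, four genes; dS_WS means: A -> 0.25, B -> 0.5
    rows = []
    for sp, vals in (
        ("A", [0.70, 0.10, 0.10, 0.10]),
        ("B", [0.50, 0.50, 0.50, 0.50]),
    ):
        for i, v in enumerate(vals):
            rows.append({"gene": f"g{i}", "species": sp, "dS_WS": v,
                         "dS_SW": 0.1, "dS_WW": 0.1, "dS_SS": 0.1,
                         "dN_WS": 0.0, "dN_SW": 0.0, "dN_WW": 0.0,
                         "dN_SS": 0.0})
    return pd.DataFrame(rows)


class TestNormalizeAndFlag:
    def test_normalization_and_strict_threshold(self):
        table = out.normalize_and_flag(_rate_frame())
        a = table[table.species == "A"].set_index("gene")
        # mean 0.25 -> 0.70 normalizes to 2.8, outlier
        assert a.loc["g0", "norm_dS_WS"] == pytest.approx(2.8)
        assert bool(a.loc["g0", "out_dS_WS"])
        # raw exactly 2.5x mean is NOT an outlier (strict inequality)
        frame = _rate_frame()
        frame.loc[(frame.species == "A") & (frame.gene == "g0"), "dS_WS"] = 0.0
        frame.loc[(frame.species == "A") & (frame.gene == "g1"), "dS_WS"] = 0.25
        mean = frame[frame.species == "A"].dS_WS.mean()
        frame.loc[(frame.species == "A") & (frame.gene == "g1"), "dS_WS"] = 2.5 * mean
        # recompute with the boundary value in place of g1
        t2 = out.normalize_and_flag(frame)
        row = t2[(t2.species == "A") & (t2.gene == "g1")]
        if row.norm_dS_WS.iloc[0] == pytest.approx(2.5):
            assert not bool(row.out_dS_WS.iloc[0])

    def test_normalized_means_are_one(self):
        table = out.normalize_and_flag(_rate_frame())
        for sp in ("A", "B"):
            vals = table.loc[table.species == sp, "norm_dS_WS"]
            assert vals.mean() == pytest.approx(1.0, abs=1e-9)

    def test_idempotence(self):
        table = out.normalize_and_flag(_rate_frame())
        renamed = table[["gene", "species"]].copy()
        for col in out.RATE_COLUMNS:
            renamed[col] = table[f"norm_{col}"]
        again = out.normalize_and_flag(renamed)
        for col in out.RATE_COLUMNS:
            assert np.allclose(
                again[f"norm_{col}"].fillna(0), renamed[col].fillna(0),
                atol=1e-12,
            )

    def test_scale_invariance_of_flags(self):
        base = out.normalize_and_flag(_rate_frame())
        scaled_frame = _rate_frame()
        mask = scaled_frame.species == "A"
        scaled_frame.loc[mask, "dS_WS"] *= 37.0
        scaled = out.normalize_and_flag(scaled_frame)
        assert (base.out_dS_WS == scaled.out_dS_WS).all()

    def test_zero_mean_category_degenerate(self):
        table = out.normalize_and_flag(_rate_frame())
        assert ("A", "dN_WS") in table.attrs["degenerate"]
        assert table.loc[table.species == "A", "norm_dN_WS"].isna().all()

    def test_missing_rates_excluded_from_mean(self):
        frame = _rate_frame()
        frame.loc[(frame.species == "A") & (frame.gene == "g3"), "dS_WS"] = np.nan
        table = out.normalize_and_flag(frame)
        a = table[table.species == "A"]
        mean = np.nanmean(frame.loc[frame.species == "A", "dS_WS"])
        assert a.set_index("gene").loc["g0", "norm_dS_WS"] == pytest.approx(0.7 / mean)


class TestOverlapAndComparisons:
    def test_outlier_overlap_set_algebra(self):
        res = out.outlier_overlap(
            {"A": {"g1", "g2"}, "B": {"g2", "g3"}}
        )
        assert res["per_species"] == {"A": 2, "B": 2}
        assert res["pairwise"][("A", "B")] == 1
        assert res["intersection"] == {"g2"}
        assert len(res["union"]) == 3

    def test_disjoint_sets(self):
        res = out.outlier_overlap({"A": {"g1"}, "B": {"g2"}})
        assert res["intersection"] == set()

    def test_identical_groups_not_significant(self, rng):
        vals = np.concatenate([rng.normal(size=50), rng.normal(size=50)])
        flags = np.array([True] * 50 + [False] * 50)
        # both groups drawn from the same distribution
        res = out.compare_groups(vals, flags, "greater")
        assert res["p_value"] > 0.01

    def test_shifted_group_is_significant(self, rng):
        vals = np.concatenate([rng.normal(size=50) + 100, rng.normal(size=50)])
        flags = np.array([True] * 50 + [False] * 50)
        res = out.compare_groups(vals, flags, "greater")
        assert res["p_value"] < 1e-6

    def test_degenerate_group_flagged(self):
        res = out.compare_groups(np.arange(5.0), np.zeros(5, dtype=bool))
        assert res["degenerate"]

    def test_chimney_fraction(self):
        table = out.normalize_and_flag(_rate_frame())
        # species A: one outlier (g0) with dS_WS 0.7 > dS_SW 0.1
        assert out.chimney_fraction(table, "A") == 1.0
        assert np.isnan(out.chimney_fraction(table, "B"))

    def test_dunn_posthoc_detects_shifted_group(self, rng):
        groups = {
            "a": rng.normal(size=80),
            "b": rng.normal(size=80),
            "c": rng.normal(size=80) + 3.0,
        }
        df = out.dunn_posthoc(groups)
        sig = df[(df.group_a == "a") & (df.group_b == "c")]
        assert sig.p_bh.iloc[0] < 1e-6
        same = df[(df.group_a == "a") & (df.group_b == "b")]
        assert same.p_bh.iloc[0] > 0.01
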