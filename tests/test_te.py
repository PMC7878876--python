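import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssrscape.detect import SSRRecord
from ssrscape.io import read_repeatmasker_out, write_repeatmasker_out
from ssrscape.te import (TECopy, assign_ssrs_to_tes, classify_epoch,
                         copies_from_frame, epoch_ssr_share,
                         family_density_ratio, family_summary,
                         load_repeatmasker, te_age)

from oracles import brute_force_assign


def make_te(start, end, family="En-Spm", divergence=0.21, seq_id="chr1",
            strand="+", split=100e6):
    age = te_age(divergence)
    return TECopy(seq_id, start, end, strand, family, "DNA", divergence,
                  age, classify_epoch(age, split))


def make_ssr(start, end, seq_id="chr1", motif="AT"):
    return SSRRecord(seq_id, start, end, motif, len(motif),
                     (end - start) / len(motif), end - start)


class TestAge:
    def test_decapod_clock_examples(self):
        # 0.21 substitutions/site at 2e-9 /site/yr -> ~105 Myr
        assert te_age(0.21) == pytest.approx(1.05e8)
        assert te_age(0.0) == 0.0
        assert te_age(0.002, 2e-9) == pytest.approx(1e6)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            te_age(0.1, 0)
        with pytest.raises(ValueError):
            te_age(-0.1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0, 1), st.integers(1, 10))
    def test_linearity(self, d, k):
        assert te_age(k * d) == pytest.approx(k * te_age(d))


class TestRepeatMaskerIO:
    def test_round_trip_and_divergence_units(self, tmp_path):
        tes = [make_te(100, 700), make_te(2000, 2600, "Gypsy", 0.264),
               make_te(5000, 5400, "Penelope", 0.02, strand="-")]
        path = tmp_path / "rm.out"
        write_repeatmasker_out(tes, path)
        df = read_repeatmasker_out(path)
        assert len(df) == 3
        assert list(df["family"]) == ["En-Spm", "Gypsy", "Penelope"]
        assert df.loc[1, "divergence"] == pytest.approx(0.264)
        copies = load_repeatmasker(path)
        assert copies[1].age == pytest.approx(1.32e8)
        assert copies[1].epoch == "ancient"
        assert copies[2].epoch == "recent"
        assert (df["start"] == [100, 2000, 5000]).all()

    def test_header_only_file(self, tmp_path):
        path = tmp_path / "empty.out"
        path.write_text("   SW   perc perc\nscore   div. del.\n\n")
        assert load_repeatmasker(path) == []

    def test_missing_divergence_yields_na_epoch(self):
        import pandas as pd
        df = pd.DataFrame([{"seq_id": "c", "start": 0, "end": 10,
                            "strand": "+", "family": "X",
                            "te_class": "DNA", "divergence": np.nan}])
        copy, = copies_from_frame(df)
        assert np.isnan(copy.age) and copy.epoch == "NA"


class TestAssignment:
    def test_zone_examples(self):
        te = make_te(1000, 2000)
        inside, = assign_ssrs_to_tes([make_ssr(1200, 1240)], [te])
        assert inside.zone == "inside" and inside.overlap_bp == 40
        up, = assign_ssrs_to_tes([make_ssr(930, 960)], [te])
        assert up.zone == "upstream_flank"
        out, = assign_ssrs_to_tes([make_ssr(700, 730)], [te])
        assert out.zone == "outside" and out.te is None
        other, = assign_ssrs_to_tes([make_ssr(1200, 1240, seq_id="chr9")],
                                    [te])
        assert other.zone == "outside"

    def test_strand_flips_flank_labels(self):
        te = make_te(1000, 2000, strand="-")
        a, = assign_ssrs_to_tes([make_ssr(930, 960)], [te])
        assert a.zone == "downstream_flank"

    def test_partition_invariant(self, small_sim):
        assignments = assign_ssrs_to_tes(small_sim["records"],
                                         small_sim["truth"].tes)
        assert len(assignments) == len(small_sim["records"])
        zones = {"inside": 0, "upstream_flank": 0, "downstream_flank": 0,
                 "outside": 0}
        for a in assignments:
            zones[a.zone] += 1
        assert sum(zones.values()) == len(small_sim["records"])

    def test_harboring_monotone_in_flank_width(self, small_sim):
        tes = small_sim["truth"].tes
        fractions = []
        for flank in (0, 100, 500):
            a = assign_ssrs_to_tes(small_sim["records"], tes, flank_bp=flank)
            s = family_summary(a, tes)
            fractions.append(s["n_harboring"].sum())
        assert fractions[0] <= fractions[1] <= fractions[2]

    def test_matches_brute_force_resolver(self, rng):
        """50 SSRs vs 10 (partly nested) TEs: identical to the all-pairs
        quadratic oracle."""
        tes = []
        for i in range(10):
            start = int(rng.integers(0, 20_000))
            tes.append(make_te(start, start + int(rng.integers(200, 3000)),
                               family=f"F{i % 3}",
                               strand="+-"[i % 2]))
        ssrs = []
        for _ in range(50):
            s = int(rng.integers(0, 25_000))
            ssrs.append(make_ssr(s, s + int(rng.integers(12, 300))))
        got = assign_ssrs_to_tes(ssrs, tes)
        expected = brute_force_assign(ssrs, tes)
        for a, (zone, idx) in zip(got, expected):
            assert a.zone == zone
            if idx is None:
                assert a.te is None
            else:
                assert a.te is tes[idx]


class TestFamilySummary:
    def test_harboring_recovery_against_truth(self, small_sim):
        truth = small_sim["truth"]
        assignments = assign_ssrs_to_tes(small_sim["records"], truth.tes)
        summary = family_summary(assignments, truth.tes)
        planted = {}
        for c in truth.te_carriage:
            n, k = planted.get(c["family"], (0, 0))
            planted[c["family"]] = (n + 1, k + bool(c["carried"]))
        by_fam = summary.groupby("family")[
            ["n_copies", "n_harboring_inside"]].sum()
        for fam, (n, k) in planted.items():
            est = by_fam.loc[fam, "n_harboring_inside"] / \
                by_fam.loc[fam, "n_copies"]
            # detector recovers the exact planted carriage
            assert est == pytest.approx(k / n, abs=3 / np.sqrt(n))

    def test_empty_family_omitted(self):
        te = make_te(0, 1000)
        summary = family_summary(assign_ssrs_to_tes([], [te]), [te])
        assert set(summary["family"]) == {"En-Spm"}
        assert summary["n_harboring"].sum() == 0

    def test_epoch_share_sums_to_te_fraction(self, small_sim):
        assignments = assign_ssrs_to_tes(small_sim["records"],
                                         small_sim["truth"].tes)
        share = epoch_ssr_share(assignments)
        in_te = sum(1 for a in assignments if a.zone != "outside")
        assert share.sum() == pytest.approx(in_te / len(assignments))


class TestDensityRatio:
    def make_summary(self, n_ssr, bp, family="Gypsy"):
        import pandas as pd
        return pd.DataFrame([{"family": family, "epoch": "recent",
                              "n_ssr": n_ssr, "family_bp": bp}])

    def test_equal_densities_zero(self):
        r = family_density_ratio(self.make_summary(100, 1_000_000),
                                 self.make_summary(100, 1_000_000))
        assert r.loc["Gypsy", "log2_density_ratio"] == 0

    def test_double_density_is_one(self):
        r = family_density_ratio(self.make_summary(10, 1_000_000),
                                 self.make_summary(5, 1_000_000))
        assert r.loc["Gypsy", "log2_density_ratio"] == pytest.approx(1.0)

    def test_planted_fourfold_recovery(self, rng):
        n = rng.poisson(400)
        m = rng.poisson(100)
        r = family_density_ratio(self.make_summary(n, 1_000_000),
                                 self.make_summary(m, 1_000_000))
        assert r.loc["Gypsy", "log2_density_ratio"] == pytest.approx(
            2.0, abs=0.5)
        assert r.loc["Gypsy", "padj"] < 0.05

    def test_zero_density_sentinel(self):
        r = family_density_ratio(self.make_summary(10, 1_000_000),
                                 self.make_summary(0, 1_000_000))
        assert np.isinf(r.loc["Gypsy", "log2_density_ratio"])
        assert r.loc["Gypsy", "flag"] == "zero_density"
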