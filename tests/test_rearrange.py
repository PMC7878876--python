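import numpy as np
import pandas as pd
import pytest

from ssrscape.detect import SSRRecord
from ssrscape.io import PAIR_COLUMNS, write_pair_tsv
from ssrscape.rearrange import (call_sites, cross_sample_validate,
                                dedupe_pairs, discordant_events, load_pairs,
                                window_tracks)
from ssrscape.simulate import RearrangementSpec, simulate_rearranged_reads

from test_te import make_ssr, make_te


def pair_frame(rows):
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def test_load_pairs_tsv_round_trip(tmp_path):
    pairs = pair_frame([
        (f"p{i}", "chr1", 100 + i, "chr1", 300 + i, "s1")
        for i in range(5)])
    path = tmp_path / "pairs.tsv"
    write_pair_tsv(pairs, path)
    loaded = load_pairs(path)
    assert len(loaded) == 5
    assert list(loaded["pos_1"]) == [100, 101, 102, 103, 104]


def test_duplicate_collapsing_matches_manual_dedup():
    rows = [("a", "chr1", 100, "chr1", 80_000, "s1"),
            ("b", "chr1", 100, "chr1", 80_000, "s1"),   # exact dup
            ("c", "chr1", 100, "chr1", 80_000, "s2"),   # other sample
            ("d", "chr1", 101, "chr1", 80_000, "s1")]
    deduped = dedupe_pairs(pair_frame(rows))
    assert len(deduped) == 3


def test_call_sites_definitional_examples():
    one = pair_frame([("p1", "chr1", 10_000, "chr1", 70_000, "s1")])
    sites = call_sites(one, min_support=1)
    assert len(sites) == 2  # both junction ends
    assert {s.position for s in sites} == {10_000, 70_000}
    assert sites[0].span == 60_000
    short = pair_frame([("p1", "chr1", 10_000, "chr1", 40_000, "s1")])
    assert call_sites(short, min_support=1) == []
    inter = pair_frame([("p1", "chr1", 10_000, "chr2", 5_000, "s1")])
    s1, s2 = call_sites(inter, min_support=1)
    assert {s1.seq_id, s2.seq_id} == {"chr1", "chr2"}
    assert s1.span == -1


def test_min_support_drops_singletons():
    rows = [("p1", "chr1", 10_000, "chr1", 500_000, "s1"),
            ("p2", "chr1", 10_400, "chr1", 500_300, "s1"),
            ("p3", "chr1", 300_000, "chr1", 900_000, "s1")]  # lone pair
    sites = call_sites(pair_frame(rows), min_support=2)
    assert len(sites) == 2
    for s in sites:
        assert s.supporting_pairs == 2
        assert set(s.pair_ids) == {"p1", "p2"}


def test_raising_max_span_never_adds_sites(rng):
    pos1 = rng.integers(0, 1_000_000, size=300)
    span = rng.integers(1_000, 200_000, size=300)
    pairs = pair_frame([(f"p{i}", "chr1", int(a), "chr1", int(a + s), "s1")
                        for i, (a, s) in enumerate(zip(pos1, span))])
    n_prev = None
    for max_span in (20_000, 50_000, 100_000, 150_000):
        n = len(discordant_events(pairs, max_span))
        if n_prev is not None:
            assert n <= n_prev
        n_prev = n


def test_simulated_breakpoints_recovered(rng):
    spec = RearrangementSpec(n_breakpoints=3)
    pairs, bps = simulate_rearranged_reads(1_000_000, spec, rng=rng)
    sites = call_sites(pairs)
    anchors = [a for bp in bps for a in bp]
    positions = [s.position for s in sites]
    for a in anchors:
        assert min(abs(p - a) for p in positions) <= 1000
    # every called site traces back to its supporting pairs
    ids = set(pairs["pair_id"])
    for s in sites:
        assert s.supporting_pairs >= 2
        assert set(s.pair_ids) <= ids


def test_zero_breakpoints_zero_sites(rng):
    spec = RearrangementSpec(n_breakpoints=0)
    spec.pair_spec.chimera_rate = 0.0
    pairs, _ = simulate_rearranged_reads(500_000, spec, rng=rng)
    assert call_sites(pairs) == []


class TestCrossSample:
    def make_sites(self, positions, sample):
        return call_sites(pair_frame([
            (f"{sample}.{i}.{j}", "chr1", p, "chr1", p + 400_000, sample)
            for i, p in enumerate(positions) for j in range(2)]))

    def test_shared_site_validated_private_not(self):
        by_sample = {
            "s1": self.make_sites([100_000], "s1"),
            "s2": self.make_sites([100_300], "s2"),
            "s3": self.make_sites([250_000], "s3"),
        }
        res = cross_sample_validate(by_sample)
        shared = res[(res["position"] - 100_000).abs() < 1000]
        assert shared["validated"].all()
        assert shared["n_samples"].iloc[0] >= 2
        private = res[(res["position"] - 250_000).abs() < 1000]
        assert not private["validated"].any()

    def test_single_sample_passthrough(self):
        res = cross_sample_validate({"s1": self.make_sites([50_000], "s1")})
        assert res["validated"].all()
        assert (res["flag"] == "single_sample_passthrough").all()


class TestWindowTracks:
    def test_fraction_definitional(self):
        ssr = [make_ssr(2_000, 7_000)]  # 5 kb in window 0
        res = window_tracks([], ssr, [], {"chr1": 20_000}, window=10_000,
                            n_permutations=10,
                            rng=np.random.default_rng(0))
        tracks = res["tracks"]
        assert tracks.loc[0, "ssr_fraction"] == 0.5
        assert tracks.loc[1, "ssr_fraction"] == 0.0

    def test_truncated_last_window_uses_actual_width(self):
        ssr = [make_ssr(10_000, 12_500)]
        res = window_tracks([], ssr, [], {"chr1": 15_000}, window=10_000,
                            n_permutations=10,
                            rng=np.random.default_rng(0))
        tracks = res["tracks"]
        assert tracks.loc[1, "width"] == 5_000
        assert tracks.loc[1, "ssr_fraction"] == 0.5

    def test_content_conservation(self, small_sim):
        recs = small_sim["records"]
        res = window_tracks([], recs, small_sim["truth"].tes,
                            {"chr1": 1_000_000}, n_permutations=10,
                            rng=np.random.default_rng(0))
        tracks = res["tracks"]
        total = (tracks["ssr_fraction"] * tracks["width"]).sum()
        merged_bp = 0
        last_end = -1
        for r in sorted(recs, key=lambda r: r.start):
            s, e = max(r.start, last_end), r.end
            if e > s:
                merged_bp += e - s
                last_end = e
            last_end = max(last_end, r.end)
        assert total == pytest.approx(merged_bp)

    def test_all_zero_sites_reports_na(self):
        res = window_tracks([], [make_ssr(0, 100)], [], {"chr1": 100_000},
                            n_permutations=10,
                            rng=np.random.default_rng(0))
        assert np.isnan(res["correlations"]["site_vs_ssr_rho"])
        assert np.isnan(res["adjacency"]["pvalue"])

    def test_planted_adjacency_detected(self, small_sim):
        recs = small_sim["records"]
        ssr_iv = [(r.start, r.end) for r in recs]
        rng = np.random.default_rng(7)
        spec = RearrangementSpec(n_breakpoints=10,
                                 ssr_bias_bp=(1_000, 20_000))
        pairs, _ = simulate_rearranged_reads(
            1_000_000, spec, ssr_intervals=ssr_iv, rng=rng)
        sites = call_sites(pairs)
        res = window_tracks(sites, recs, small_sim["truth"].tes,
                            {"chr1": 1_000_000}, n_permutations=500,
                            rng=rng)
        assert res["adjacency"]["pvalue"] < 0.05
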