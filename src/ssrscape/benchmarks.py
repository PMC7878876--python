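"""Recovery benchmarks on synthetic genomes with known truth.

Each function runs one planted-truth experiment end to end — generate,
analyse with the package, compare against the ledger — and returns the
measured quantities.  They power the validation suite and the
reproduction script; sizes default to desk scale (a few Mb, seconds to
a couple of minutes each).
"""

from __future__ import annotations

import numpy as np

from . import rearrange
from .detect import find_ssrs_genome
from .modes import detect_modes
from .peaks import intervals_from_records, stratified_enrichment
from .profile import compare_profiles, profile
from .simulate import (PeakSpec, RearrangementSpec, SimConfig,
                       expected_ssr_count, simulate_genome, simulate_peaks,
                       simulate_rearranged_reads)
from .te import assign_ssrs_to_tes, epoch_ssr_share, family_summary


def scaled_config(seed: int, genome_length: int) -> SimConfig:
    """Default study configuration with TE copy numbers scaled to the
    genome size (per-Mb planting rates are size-invariant already)."""
    cfg = SimConfig(seed=seed, genome_length=genome_length)
    scale = genome_length / 5_000_000
    for fam in cfg.te_families:
        fam.copy_number = max(10, int(round(fam.copy_number * scale)))
    cfg.genes.n_genes = max(10, int(round(cfg.genes.n_genes * scale)))
    return cfg


def density_and_harboring_recovery(seed: int,
                                   genome_length: int = 5_000_000) -> dict:
    """Recover the planted (AT)n density and the per-epoch TE
    SSR-harboring probabilities on one default synthetic genome."""
    cfg = scaled_config(seed, genome_length)
    seqs, truth = simulate_genome(cfg)
    records = find_ssrs_genome(seqs)
    prof = profile(records, genome_length)

    expected_at = expected_ssr_count(cfg, "AT")
    detected_at = int(prof.per_class["count"].get("AT", 0))
    planted_at = sum(1 for r in truth.ssrs if r.motif == "AT")

    assignments = assign_ssrs_to_tes(records, truth.tes)
    summary = family_summary(assignments, truth.tes)
    by_epoch = summary.groupby("epoch")[
        ["n_copies", "n_harboring_inside"]].sum()
    harboring = {}
    planted_probs = {"ancient": 0.9, "recent": 0.5}
    for epoch in ("ancient", "recent"):
        n = int(by_epoch["n_copies"].get(epoch, 0))
        k = int(by_epoch["n_harboring_inside"].get(epoch, 0))
        p0 = planted_probs[epoch]
        se = float(np.sqrt(p0 * (1 - p0) / n)) if n else np.nan
        harboring[epoch] = {"n_copies": n, "estimate": k / n if n else np.nan,
                            "planted": p0, "binomial_se": se}
    share = epoch_ssr_share(assignments)
    return {
        "genome_length": genome_length,
        "expected_at_count": expected_at,
        "planted_at_count": planted_at,
        "detected_at_count": detected_at,
        "detected_at_density_per_mb": detected_at / (genome_length / 1e6),
        "planted_at_rate_per_mb": 3000.0,
        "at_z": (detected_at - expected_at) / np.sqrt(expected_at),
        "harboring": harboring,
        "ancient_ssr_share": float(share.get("ancient", np.nan)),
        "total_ssr_count": prof.total_count,
        "total_density_per_mb": prof.total_density,
        "genome_fraction": prof.total_fraction,
    }


def rearrangement_benchmark(seed: int, n_seeds: int = 20,
                            genome_length: int = 2_000_000,
                            n_breakpoints: int = 10,
                            coverage: float = 30.0,
                            tolerance: int = 1000) -> dict:
    """Recall/precision of the site caller over seeded simulations.

    A planted junction anchor counts as recovered when a called site
    lies within *tolerance* bp; a called site is correct when it lies
    within tolerance of any planted anchor.
    """
    recalls, precisions = [], []
    spec = RearrangementSpec(n_breakpoints=n_breakpoints)
    spec.pair_spec.coverage = coverage
    for i in range(n_seeds):
        rng = np.random.default_rng(seed + i)
        pairs, bps = simulate_rearranged_reads(genome_length, spec, rng=rng)
        sites = rearrange.call_sites(pairs)
        anchors = [a for bp in bps for a in bp]
        positions = np.array([s.position for s in sites]) if sites else \
            np.empty(0)
        rec = np.mean([np.any(np.abs(positions - a) <= tolerance)
                       for a in anchors]) if anchors else np.nan
        prec = np.mean([np.any(np.abs(np.array(anchors) - p) <= tolerance)
                        for p in positions]) if len(positions) else np.nan
        recalls.append(float(rec))
        precisions.append(float(prec))
    return {"n_seeds": n_seeds, "recalls": recalls, "precisions": precisions,
            "median_recall": float(np.median(recalls)),
            "median_precision": float(np.median(precisions))}


def adjacency_benchmark(seed: int, n_seeds: int = 20,
                        genome_length: int = 1_000_000,
                        bias_bp: tuple = (1_000, 20_000),
                        n_permutations: int = 500) -> dict:
    """Fraction of seeded runs where breakpoints planted near SSR-dense
    blocks give a significant adjacency statistic (p < 0.05)."""
    cfg = scaled_config(seed, genome_length)
    seqs, truth = simulate_genome(cfg)
    records = find_ssrs_genome(seqs)
    ssr_iv = [(r.start, r.end) for r in records]
    seq_lengths = {cfg.seq_id: genome_length}
    n_sig = 0
    pvals = []
    for i in range(n_seeds):
        rng = np.random.default_rng(seed + 1000 + i)
        spec = RearrangementSpec(n_breakpoints=10, ssr_bias_bp=bias_bp)
        pairs, _ = simulate_rearranged_reads(
            genome_length, spec, ssr_intervals=ssr_iv, rng=rng)
        sites = rearrange.call_sites(pairs)
        res = rearrange.window_tracks(sites, records, truth.tes,
                                      seq_lengths,
                                      n_permutations=n_permutations, rng=rng)
        p = res["adjacency"]["pvalue"]
        pvals.append(float(p))
        n_sig += p < 0.05
    return {"n_seeds": n_seeds, "pvalues": pvals,
            "fraction_significant": n_sig / n_seeds}


def bimodality_benchmark(seed: int, n_runs: int = 100, n: int = 2000) -> dict:
    """Mode-count recovery: a two-component mixture separated by >=4 sd
    vs a single-component null, over seeded draws."""
    bi_correct = uni_correct = valley_in_range = 0
    for i in range(n_runs):
        rng = np.random.default_rng(seed + i)
        mix = np.concatenate([rng.normal(20, 3, int(n * 0.7)),
                              rng.normal(120, 20, n - int(n * 0.7))])
        rep = detect_modes(np.clip(mix, 5, None))
        bi_correct += rep.n_modes == 2
        if rep.n_modes == 2 and 40 <= rep.valley_threshold <= 90:
            valley_in_range += 1
        null = np.clip(rng.normal(20, 3, n), 5, None)
        uni_correct += detect_modes(null).n_modes == 1
    return {"n_runs": n_runs,
            "bimodal_detection_rate": bi_correct / n_runs,
            "valley_in_range_rate": valley_in_range / n_runs,
            "unimodal_correct_rate": uni_correct / n_runs}


def peak_trend_benchmark(seed: int, n_null: int = 100,
                         genome_length: int = 1_000_000,
                         n_bootstrap: int = 300) -> dict:
    """Planted monotone peak enrichment recovery plus the false-trend
    rate on a flat (no-enrichment) null."""
    cfg = scaled_config(seed, genome_length)
    seqs, _ = simulate_genome(cfg)
    records = find_ssrs_genome(seqs)
    feats = intervals_from_records(records)
    ssr_iv = [(r.start, r.end) for r in records]

    rng = np.random.default_rng(seed)
    steep = PeakSpec(n_all=800, n_diff=600)
    allp, diffp, _ = simulate_peaks(genome_length, ssr_iv, steep, rng=rng)
    planted = stratified_enrichment(allp, diffp, feats,
                                    n_bootstrap=1000, rng=rng)
    flat = PeakSpec(n_all=600, n_diff=400, base_overlap_prob=0.15,
                    stratum_overlap_probs=(0.15, 0.15, 0.15))
    false = 0
    null_ps = []
    for i in range(n_null):
        rng = np.random.default_rng(seed + 5000 + i)
        allp, diffp, _ = simulate_peaks(genome_length, ssr_iv, flat, rng=rng)
        res = stratified_enrichment(allp, diffp, feats,
                                    n_bootstrap=n_bootstrap, rng=rng)
        null_ps.append(float(res["trend_p"]))
        false += res["trend_p"] < 0.05
    contents = planted["table"]["content"].tolist()
    return {"planted_trend_p": float(planted["trend_p"]),
            "planted_contents": contents,
            "planted_monotone": bool(np.all(np.diff(contents) > 0)),
            "n_null": n_null, "null_false_trend_rate": false / n_null}


def profile_type1_benchmark(seed: int, n_pairs: int = 20,
                            genome_length: int = 2_000_000,
                            min_count: int = 5) -> dict:
    """Fraction of motif classes flagged (BH-adjusted p < 0.05) when
    comparing genome pairs generated from identical parameters.

    Classes with fewer than *min_count* records in both genomes are
    ignored (their chi-square approximation is meaningless)."""
    flagged = total = 0
    for i in range(n_pairs):
        profs = []
        for sub in range(2):
            cfg = scaled_config(seed + 2 * i + sub * 100_003, genome_length)
            seqs, _ = simulate_genome(cfg)
            profs.append(profile(find_ssrs_genome(seqs), genome_length,
                                 f"g{sub}"))
        table = compare_profiles(profs[0], profs[1]).table
        table = table[(table["count_a"] + table["count_b"]) >= min_count]
        table = table[table["padj"].notna()]
        flagged += int((table["padj"] < 0.05).sum())
        total += len(table)
    return {"n_pairs": n_pairs, "n_class_tests": total,
            "n_flagged": flagged,
            "flagged_fraction": flagged / total if total else np.nan}
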