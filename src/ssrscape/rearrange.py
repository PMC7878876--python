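"""Discordant read-pair rearrangement calling and repeat-track correlation.

A read pair whose mates map to different sequences, or farther apart
than a span threshold (50 kb by default, well above any insert size),
is evidence for a rearrangement.  Evidence is clustered into candidate
sites, optionally cross-validated across samples, aggregated into
fixed-width window tracks (10 kb by default) alongside SSR and TE
content, and a circular-permutation test asks whether rearrangement
hotspots sit near SSR-dense windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MAX_SPAN = 50_000
DEFAULT_CLUSTER_BP = 1_000
DEFAULT_MIN_SUPPORT = 2
DEFAULT_WINDOW = 10_000


@dataclass
class RearrangementSite:
    seq_id: str
    position: int            # cluster midpoint of anchor positions
    span: float              # median same-sequence span; -1 = inter-sequence
    supporting_pairs: int
    samples_supporting: frozenset = field(default_factory=frozenset)
    pair_ids: tuple = ()


def dedupe_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Collapse pairs with identical coordinates (PCR duplicates)."""
    return pairs.drop_duplicates(
        subset=["seq_id_1", "pos_1", "seq_id_2", "pos_2", "sample_id"])


def load_pairs(path, min_mapq: int = 20) -> pd.DataFrame:
    """Load read pairs from a 6-column TSV or SAM/BAM, deduplicated."""
    from . import io as _io

    path = str(path)
    if path.endswith((".sam", ".bam", ".cram")):
        pairs = _io.read_pairs_sam(path, min_mapq=min_mapq)
    else:
        pairs = _io.read_pair_tsv(path)
    return dedupe_pairs(pairs)


def discordant_events(pairs: pd.DataFrame, max_span: int = DEFAULT_MAX_SPAN
                      ) -> pd.DataFrame:
    """Expand discordant pairs into anchor-level evidence.

    Every discordant pair yields one event per mapped anchor: the two
    junction ends of a same-sequence long-span pair (span recorded) and
    both mates of an inter-sequence pair (span -1).  Counting both
    anchors keeps per-window tracks symmetric and puts evidence at the
    breakpoint ends rather than halfway between them.
    """
    same = pairs["seq_id_1"] == pairs["seq_id_2"]
    span = (pairs["pos_2"] - pairs["pos_1"]).abs()
    discordant = (~same) | (span > max_span)
    sel = pairs[discordant]
    events = []
    for side in (1, 2):
        if len(sel):
            events.append(pd.DataFrame({
                "seq_id": sel[f"seq_id_{side}"],
                "position": sel[f"pos_{side}"],
                "span": span[sel.index].where(same[sel.index], -1),
                "sample_id": sel["sample_id"],
                "pair_id": sel["pair_id"],
            }))
    if not events:
        return pd.DataFrame(columns=["seq_id", "position", "span",
                                     "sample_id", "pair_id"])
    return pd.concat(events, ignore_index=True)


def call_sites(pairs: pd.DataFrame, max_span: int = DEFAULT_MAX_SPAN,
               cluster_bp: int = DEFAULT_CLUSTER_BP,
               min_support: int = DEFAULT_MIN_SUPPORT
               ) -> list[RearrangementSite]:
    """Cluster discordant evidence into candidate rearrangement sites.

    Evidence on the same sequence closer than *cluster_bp* merges into
    one site; sites supported by fewer than *min_support* pairs are
    dropped.  Every site retains the ids of its supporting pairs.
    """
    ev = discordant_events(pairs, max_span)
    sites: list[RearrangementSite] = []
    for seq_id, grp in ev.groupby("seq_id", sort=True):
        grp = grp.sort_values("position", kind="mergesort")
        pos = grp["position"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > cluster_bp) + 1
        for chunk in np.split(np.arange(len(pos)), breaks):
            sub = grp.iloc[chunk]
            if len(sub) < min_support:
                continue
            spans = sub["span"].to_numpy()
            intra = spans[spans >= 0]
            sites.append(RearrangementSite(
                seq_id=seq_id,
                position=int(np.median(sub["position"])),
                span=float(np.median(intra)) if intra.size else -1.0,
                supporting_pairs=len(sub),
                samples_supporting=frozenset(sub["sample_id"]),
                pair_ids=tuple(sub["pair_id"])))
    return sites


def cross_sample_validate(sites_by_sample: dict[str, list[RearrangementSite]],
                          cluster_bp: int = DEFAULT_CLUSTER_BP,
                          min_samples: int = 2) -> pd.DataFrame:
    """Keep sites supported in >= *min_samples* samples within
    *cluster_bp*.  With a single sample all sites pass (with a flag).
    Returns one row per merged site with its sample-support vector."""
    rows = []
    for sample, sites in sites_by_sample.items():
        for s in sites:
            rows.append((s.seq_id, s.position, sample, s.supporting_pairs))
    df = pd.DataFrame(rows, columns=["seq_id", "position", "sample_id",
                                     "supporting_pairs"])
    single = len(sites_by_sample) < 2
    out = []
    for seq_id, grp in df.groupby("seq_id", sort=True):
        grp = grp.sort_values("position", kind="mergesort")
        pos = grp["position"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > cluster_bp) + 1
        for chunk in np.split(np.arange(len(pos)), breaks):
            sub = grp.iloc[chunk]
            samples = sorted(set(sub["sample_id"]))
            out.append((seq_id, int(np.median(sub["position"])),
                        len(samples), ",".join(samples),
                        int(sub["supporting_pairs"].sum()),
                        single or len(samples) >= min_samples))
    res = pd.DataFrame(out, columns=[
        "seq_id", "position", "n_samples", "samples", "supporting_pairs",
        "validated"])
    if single:
        res["flag"] = "single_sample_passthrough"
    return res


def _interval_window_bp(starts, ends, n_windows: int, window: int,
                        seq_len: int) -> np.ndarray:
    """bp of interval coverage per window (intervals may be unmerged;
    caller merges first if double counting matters)."""
    cov = np.zeros(n_windows)
    for s, e in zip(starts, ends):
        s, e = max(0, int(s)), min(int(e), seq_len)
        if e <= s:
            continue
        w0, w1 = s // window, (e - 1) // window
        if w0 == w1:
            cov[w0] += e - s
        else:
            cov[w0] += (w0 + 1) * window - s
            cov[w1] += e - w1 * window
            if w1 > w0 + 1:
                cov[w0 + 1:w1] += window
    return cov


def _merge_intervals(starts, ends):
    order = np.argsort(starts, kind="mergesort")
    ms, me = [], []
    for s, e in zip(np.asarray(starts)[order], np.asarray(ends)[order]):
        if ms and s <= me[-1]:
            me[-1] = max(me[-1], e)
        else:
            ms.append(s)
            me.append(e)
    return np.array(ms), np.array(me)


def window_tracks(sites, ssrs, tes, seq_lengths: dict[str, int],
                  window: int = DEFAULT_WINDOW,
                  n_permutations: int = 1000,
                  rng: np.random.Generator | None = None,
                  hotspot_quantile: float = 0.9) -> dict:
    """Per-window rearrangement/SSR/TE tracks plus association report.

    Returns {"tracks": DataFrame, "correlations": dict, "adjacency":
    dict}.  The adjacency statistic is, over hotspot windows (top decile
    of site counts), the mean distance in windows to the nearest
    SSR-content peak window, with a circular-shift permutation null for
    the SSR track.  An all-zero site track reports NA correlations.
    """
    if rng is None:
        rng = np.random.default_rng()
    frames = []
    for seq_id, seq_len in sorted(seq_lengths.items()):
        n_win = max(1, -(-seq_len // window))
        counts = np.zeros(n_win)
        for s in sites:
            if s.seq_id == seq_id:
                counts[min(s.position // window, n_win - 1)] += 1
        widths = np.full(n_win, window, dtype=float)
        if seq_len % window:
            widths[-1] = seq_len % window
        ssr_sel = [r for r in ssrs if r.seq_id == seq_id]
        te_sel = [t for t in tes if t.seq_id == seq_id]
        ssr_bp = np.zeros(n_win)
        if ssr_sel:
            ms, me = _merge_intervals([r.start for r in ssr_sel],
                                      [r.end for r in ssr_sel])
            ssr_bp = _interval_window_bp(ms, me, n_win, window, seq_len)
        te_bp = np.zeros(n_win)
        if te_sel:
            ms, me = _merge_intervals([t.start for t in te_sel],
                                      [t.end for t in te_sel])
            te_bp = _interval_window_bp(ms, me, n_win, window, seq_len)
        frames.append(pd.DataFrame({
            "seq_id": seq_id,
            "window_start": np.arange(n_win) * window,
            "width": widths.astype(int),
            "site_count": counts,
            "ssr_fraction": ssr_bp / widths,
            "te_fraction": te_bp / widths,
        }))
    tracks = pd.concat(frames, ignore_index=True)

    correlations: dict[str, float] = {}
    if tracks["site_count"].sum() == 0 or len(tracks) < 3:
        correlations = {"site_vs_ssr_rho": np.nan, "site_vs_ssr_p": np.nan,
                        "site_vs_te_rho": np.nan, "site_vs_te_p": np.nan}
    else:
        for name in ("ssr", "te"):
            rho, p = stats.spearmanr(tracks["site_count"],
                                     tracks[f"{name}_fraction"])
            correlations[f"site_vs_{name}_rho"] = float(rho)
            correlations[f"site_vs_{name}_p"] = float(p)

    adjacency = _adjacency_test(tracks, n_permutations, rng,
                                hotspot_quantile)
    return {"tracks": tracks, "correlations": correlations,
            "adjacency": adjacency}


def _adjacency_test(tracks: pd.DataFrame, n_permutations: int,
                    rng: np.random.Generator, q: float) -> dict:
    counts = tracks["site_count"].to_numpy()
    ssr = tracks["ssr_fraction"].to_numpy()
    if counts.sum() == 0 or len(counts) < 10:
        return {"statistic": np.nan, "pvalue": np.nan, "n_hotspots": 0}
    c_thr = max(np.quantile(counts, q), 1e-12)
    hot = np.flatnonzero(counts >= c_thr)
    s_thr = np.quantile(ssr, q)
    peaks = ssr >= s_thr
    if hot.size == 0 or not peaks.any():
        return {"statistic": np.nan, "pvalue": np.nan,
                "n_hotspots": int(hot.size)}

    def mean_dist(peak_mask: np.ndarray) -> float:
        idx = np.flatnonzero(peak_mask)
        d = np.abs(hot[:, None] - idx[None, :]).min(axis=1)
        return float(d.mean())

    obs = mean_dist(peaks)
    n = len(counts)
    shifts = rng.integers(1, n, size=n_permutations)
    null = np.array([mean_dist(np.roll(peaks, k)) for k in shifts])
    pvalue = (1 + np.sum(null <= obs)) / (n_permutations + 1)
    return {"statistic": obs, "pvalue": float(pvalue),
            "n_hotspots": int(hot.size), "null_mean": float(null.mean())}
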