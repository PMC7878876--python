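"""SSR/TE content of chromatin-accessibility peaks.

Measures the base-pair fraction of peak sequence covered by SSRs (or
TEs), overall and stratified by the peaks' differential-test p-values,
and tests whether content rises with differential significance using a
stratified bootstrap over peaks.  Differential p-values are consumed
from upstream peak callers, never computed here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_THRESHOLDS = (1e-3, 1e-5, 1e-10)


def _merge(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping intervals per seq_id (prevents double counting)."""
    out = []
    for seq_id, grp in df.groupby("seq_id", sort=True):
        grp = grp.sort_values("start", kind="mergesort")
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((seq_id, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((seq_id, cur_s, cur_e))
    return pd.DataFrame(out, columns=["seq_id", "start", "end"])


def intervals_from_records(records) -> pd.DataFrame:
    """Interval frame from objects with seq_id/start/end attributes."""
    return pd.DataFrame({
        "seq_id": [r.seq_id for r in records],
        "start": [r.start for r in records],
        "end": [r.end for r in records],
    })


def _overlap_bp_per_peak(peaks: pd.DataFrame, merged: pd.DataFrame
                         ) -> np.ndarray:
    """bp of merged-feature overlap for every peak row."""
    out = np.zeros(len(peaks))
    by_seq = {k: g for k, g in merged.groupby("seq_id")}
    for seq_id, grp in peaks.groupby("seq_id"):
        feats = by_seq.get(seq_id)
        if feats is None:
            continue
        fs = feats["start"].to_numpy()
        fe = feats["end"].to_numpy()
        ps = grp["start"].to_numpy()
        pe = grp["end"].to_numpy()
        # merged features are sorted and disjoint -> windowed sweep
        lo = np.searchsorted(fe, ps, side="right")
        hi = np.searchsorted(fs, pe, side="left")
        vals = np.zeros(len(grp))
        for i, (s, e, a, b) in enumerate(zip(ps, pe, lo, hi)):
            if b > a:
                vals[i] = np.sum(np.minimum(fe[a:b], e)
                                 - np.maximum(fs[a:b], s))
        out[grp.index.to_numpy()] = vals
    return out


def content_in_peaks(peaks: pd.DataFrame, features: pd.DataFrame) -> float:
    """Fraction of total peak bp covered by features (features merged
    first).  Peaks need seq_id/start/end columns; raises on zero total
    peak bp."""
    peaks = peaks.reset_index(drop=True)
    total = float((peaks["end"] - peaks["start"]).sum())
    if total <= 0:
        raise ValueError("content_in_peaks: zero total peak bp")
    if len(features) == 0:
        return 0.0
    merged = _merge(features)
    return float(_overlap_bp_per_peak(peaks, merged).sum() / total)


def stratified_enrichment(all_peaks: pd.DataFrame, diff_peaks: pd.DataFrame,
                          features: pd.DataFrame,
                          thresholds=DEFAULT_THRESHOLDS,
                          n_bootstrap: int = 1000,
                          rng: np.random.Generator | None = None) -> dict:
    """Feature content for all peaks and nested differential strata.

    diff_peaks must carry a ``diff_p`` column; stratum at threshold t is
    {diff_p < t}, so strata are nested by construction.  The increasing
    trend of content across strata is tested by bootstrapping peaks and
    recomputing the slope of content against stratum rank; the reported
    one-sided p-value is the (add-one corrected) bootstrap fraction of
    non-positive slopes.

    Returns {"table": DataFrame, "trend_slope": float, "trend_p": float}.
    """
    if rng is None:
        rng = np.random.default_rng()
    thresholds = sorted(thresholds, reverse=True)  # loosest first
    merged = _merge(features) if len(features) else features
    rows = []

    def stratum_content(peaks: pd.DataFrame) -> float:
        if len(peaks) == 0:
            return np.nan
        if len(merged) == 0:
            return 0.0
        peaks = peaks.reset_index(drop=True)
        total = float((peaks["end"] - peaks["start"]).sum())
        return float(_overlap_bp_per_peak(peaks, merged).sum() / total)

    rows.append(("all_peaks", np.nan, len(all_peaks),
                 stratum_content(all_peaks)))
    strata: list[pd.DataFrame] = []
    for t in thresholds:
        sub = diff_peaks[diff_peaks["diff_p"] < t]
        strata.append(sub)
        rows.append((f"diff_p<{t:g}", t, len(sub), stratum_content(sub)))
    table = pd.DataFrame(rows, columns=["stratum", "threshold", "n_peaks",
                                        "content"])

    # bootstrap trend over diff peaks: slope of content vs stratum rank
    diff = diff_peaks.reset_index(drop=True)
    if len(diff) == 0 or len(merged) == 0:
        return {"table": table, "trend_slope": np.nan, "trend_p": np.nan}
    ov = _overlap_bp_per_peak(diff, merged)
    widths = (diff["end"] - diff["start"]).to_numpy(dtype=float)
    pvals = diff["diff_p"].to_numpy()
    masks = [pvals < t for t in thresholds]
    ranks = np.arange(len(thresholds), dtype=float)

    def slope(idx: np.ndarray) -> float:
        contents = []
        for m in masks:
            sel = idx[m[idx]]
            if sel.size == 0 or widths[sel].sum() == 0:
                return np.nan
            contents.append(ov[sel].sum() / widths[sel].sum())
        contents = np.asarray(contents)
        r = ranks[:len(contents)]
        return float(np.polyfit(r, contents, 1)[0])

    all_idx = np.arange(len(diff))
    obs = slope(all_idx)
    boots = []
    for _ in range(n_bootstrap):
        b = slope(rng.integers(0, len(diff), size=len(diff)))
        if not np.isnan(b):
            boots.append(b)
    if not boots:
        return {"table": table, "trend_slope": obs, "trend_p": np.nan}
    boots = np.asarray(boots)
    trend_p = (1 + np.sum(boots <= 0)) / (len(boots) + 1)
    return {"table": table, "trend_slope": obs, "trend_p": float(trend_p)}


def annotate_genes_near_peaks(peaks: pd.DataFrame, genes: pd.DataFrame,
                              window_bp: int = 2000) -> pd.DataFrame:
    """One row per (gene, peak) where the gene body extended by
    *window_bp* overlaps the peak.  genes needs seq_id/start/end and an
    id column (``gene_id`` or ``id``)."""
    id_col = "gene_id" if "gene_id" in genes.columns else "id"
    rows = []
    for seq_id, grp in peaks.groupby("seq_id"):
        gsel = genes[genes["seq_id"] == seq_id]
        if gsel.empty:
            continue
        gs = gsel["start"].to_numpy() - window_bp
        ge = gsel["end"].to_numpy() + window_bp
        ids = gsel[id_col].to_numpy()
        for row in grp.itertuples():
            hit = (gs < row.end) & (ge > row.start)
            for gid in ids[hit]:
                rows.append((gid, getattr(row, "peak_id", row.Index),
                             seq_id, row.start, row.end))
    return pd.DataFrame(rows, columns=["gene_id", "peak_id", "seq_id",
                                       "peak_start", "peak_end"])
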