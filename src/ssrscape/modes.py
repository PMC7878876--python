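"""Short/long SSR length-mode separation.

SSR length distributions of some motif classes are bimodal: a
slippage-scale short population and an expansion-scale long population.
Modes are called on a kernel-density estimate of log10(length)
(Silverman bandwidth by default), peaks below a prominence floor are
ignored, and for a bimodal class the valley between the two modes
becomes the short/long threshold.  The thresholds used for the shrimp
comparison (long (AT)n > 65 bp; long (AAT)n > 35 bp) ship as the named
preset ``paper-2021``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde
from statsmodels.stats.multitest import multipletests

from .detect import SSRRecord
from .te import TESSRAssignment

#: published manual short/long cuts, bp, per motif class
PRESETS = {"paper-2021": {"AT": 65.0, "AAT": 35.0}}


@dataclass
class ModeConfig:
    bandwidth: float | None = None      # KDE bandwidth factor; None = Silverman
    grid_points: int = 512
    min_prominence: float = 0.05        # fraction of max density
    min_n: int = 50


@dataclass
class LengthModeReport:
    motif: str
    n: int
    hist_edges: np.ndarray = field(repr=False)
    hist_counts: np.ndarray = field(repr=False)
    n_modes: int = 1
    mode_positions: list[float] = field(default_factory=list)  # bp
    valley_threshold: float | None = None                      # bp
    short_count: int = 0
    long_count: int = 0
    flag: str = ""


def detect_modes(lengths, config: ModeConfig | None = None,
                 motif: str = "") -> LengthModeReport:
    """Call 1 vs 2 modes in an SSR length distribution.

    KDE on log10(length); local maxima with prominence >=
    ``min_prominence`` x max density are modes.  With two modes the
    valley (density argmin between them) is the short/long threshold.
    Below ``min_n`` observations the class is flagged "insufficient"
    and reported unimodal with no threshold.
    """
    if config is None:
        config = ModeConfig()
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        raise ValueError("detect_modes: empty length list")
    edges = np.histogram_bin_edges(lengths, bins=min(30, max(5, lengths.size)))
    counts, _ = np.histogram(lengths, bins=edges)
    report = LengthModeReport(motif=motif, n=int(lengths.size),
                              hist_edges=edges, hist_counts=counts)
    if lengths.size < config.min_n:
        report.flag = "insufficient"
        return report
    x = np.log10(lengths)
    if np.ptp(x) == 0:
        report.mode_positions = [float(lengths[0])]
        return report
    kde = gaussian_kde(x, bw_method=config.bandwidth)
    grid = np.linspace(x.min() - 0.1, x.max() + 0.1, config.grid_points)
    dens = kde(grid)
    peaks, props = find_peaks(dens, prominence=config.min_prominence
                              * dens.max())
    if peaks.size == 0:  # plateau edge case: take the argmax
        peaks = np.array([int(np.argmax(dens))])
        props = {"prominences": np.array([dens.max()])}
    if peaks.size > 2:
        top2 = np.sort(np.argsort(props["prominences"])[-2:])
        peaks = peaks[top2]
    report.mode_positions = [float(10 ** grid[p]) for p in peaks]
    report.n_modes = min(len(peaks), 2)
    if report.n_modes == 2:
        lo, hi = peaks[0], peaks[1]
        valley = lo + int(np.argmin(dens[lo:hi + 1]))
        report.valley_threshold = float(10 ** grid[valley])
        labels = classify_short_long_lengths(lengths,
                                             report.valley_threshold)
        report.short_count = int((~labels).sum())
        report.long_count = int(labels.sum())
    return report


def classify_short_long_lengths(lengths, threshold_bp: float) -> np.ndarray:
    """Boolean array: True = long (strictly greater than the threshold)."""
    if threshold_bp <= 0:
        raise ValueError("threshold must be > 0")
    return np.asarray(lengths, dtype=float) > threshold_bp


def classify_short_long(ssrs: list[SSRRecord], threshold_bp: float
                        ) -> pd.DataFrame:
    """Label records short/long at a threshold (ties at the threshold
    are short).  Returns a DataFrame aligned with the input order."""
    is_long = classify_short_long_lengths([r.length for r in ssrs],
                                          threshold_bp)
    return pd.DataFrame({
        "seq_id": [r.seq_id for r in ssrs],
        "start": [r.start for r in ssrs],
        "motif": [r.motif for r in ssrs],
        "length": [r.length for r in ssrs],
        "label": np.where(is_long, "long", "short"),
    })


def te_short_long_table(assignments: list[TESSRAssignment],
                        labels: pd.DataFrame) -> pd.DataFrame:
    """Per TE family: copies carrying >=1 long vs >=1 short SSR.

    labels must come from :func:`classify_short_long` on the same SSR
    list (aligned by order).  Two-proportion chi-square per family with
    BH adjustment; families without copies are omitted.
    """
    if len(assignments) != len(labels):
        raise ValueError("labels not aligned with assignments")
    per_te: dict[int, dict] = {}
    te_objects: dict[int, object] = {}
    for a, label in zip(assignments, labels["label"]):
        if a.te is None or a.zone == "outside":
            continue
        key = id(a.te)
        te_objects[key] = a.te
        d = per_te.setdefault(key, {"short": False, "long": False})
        d[label] = True
    rows: dict[str, list[int]] = {}
    for key, d in per_te.items():
        fam = te_objects[key].family
        n_long, n_short, n = rows.setdefault(fam, [0, 0, 0])
        rows[fam] = [n_long + d["long"], n_short + d["short"], n + 1]
    out_rows = []
    for fam, (n_long, n_short, n) in sorted(rows.items()):
        tbl = np.array([[n_long, n - n_long], [n_short, n - n_short]])
        if n_long + n_short > 0 and tbl.sum(axis=0).min() > 0:
            p = float(sstats.chi2_contingency(tbl, correction=False)[1])
        else:
            p = np.nan
        out_rows.append((fam, n, n_long, n_short, p))
    out = pd.DataFrame(out_rows, columns=[
        "family", "n_copies_with_ssr", "n_with_long", "n_with_short",
        "pvalue"]).set_index("family")
    mask = out["pvalue"].notna()
    out["padj"] = np.nan
    if mask.any():
        out.loc[mask, "padj"] = multipletests(
            out.loc[mask, "pvalue"], method="fdr_bh")[1]
    return out
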