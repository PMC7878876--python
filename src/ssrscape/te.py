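"""TE copy dating and SSR-TE co-localization.

A transposable-element copy is dated from its divergence to the family
consensus under a molecular clock (default 2e-9 substitutions per site
per year, the decapod rate), classified into an ancient or recent epoch
relative to a configurable split time, and SSRs are assigned to TE
bodies or their 100 bp flanks to quantify which element families carry
the genome's SSR load.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .detect import SSRRecord
from .io import read_repeatmasker_out

#: decapod molecular clock, substitutions per site per year
DEFAULT_SUBSTITUTION_RATE = 2e-9
#: default ancient/recent split, years
DEFAULT_SPLIT_TIME = 100e6
DEFAULT_FLANK_BP = 100


@dataclass(frozen=True)
class TECopy:
    """One annotated repeat-element copy."""

    seq_id: str
    start: int
    end: int
    strand: str
    family: str
    te_class: str
    divergence: float   # substitutions/site vs consensus, fraction; NaN if unknown
    age: float          # years; NaN if divergence unknown
    epoch: str          # "ancient" | "recent" | "NA"

    @property
    def length(self) -> int:
        return self.end - self.start


def te_age(divergence: float, rate: float = DEFAULT_SUBSTITUTION_RATE
           ) -> float:
    """Age in years of a TE copy: divergence / substitution rate.

    The consensus approximates the ancestral element, so the full
    divergence (not half) accrues on the copy's branch.
    """
    if rate <= 0:
        raise ValueError("substitution rate must be > 0")
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    return divergence / rate


def classify_epoch(age: float, split_time: float = DEFAULT_SPLIT_TIME) -> str:
    if np.isnan(age):
        return "NA"
    return "ancient" if age >= split_time else "recent"


def copies_from_frame(df: pd.DataFrame,
                      rate: float = DEFAULT_SUBSTITUTION_RATE,
                      split_time: float = DEFAULT_SPLIT_TIME
                      ) -> list[TECopy]:
    """Build dated TECopy records from a RepeatMasker-style DataFrame."""
    copies = []
    for row in df.itertuples():
        div = getattr(row, "divergence", np.nan)
        div = np.nan if div is None else float(div)
        age = np.nan if np.isnan(div) else te_age(div, rate)
        copies.append(TECopy(
            seq_id=row.seq_id, start=int(row.start), end=int(row.end),
            strand=getattr(row, "strand", "+"), family=row.family,
            te_class=getattr(row, "te_class", "other"),
            divergence=div, age=age, epoch=classify_epoch(age, split_time)))
    return copies


def load_repeatmasker(path, rate: float = DEFAULT_SUBSTITUTION_RATE,
                      split_time: float = DEFAULT_SPLIT_TIME
                      ) -> list[TECopy]:
    """Load TE copies from a RepeatMasker .out table and date them."""
    return copies_from_frame(read_repeatmasker_out(path), rate, split_time)


@dataclass(frozen=True)
class TESSRAssignment:
    """Zone of one SSR relative to the TE set."""

    ssr: SSRRecord
    te: TECopy | None
    zone: str        # inside | upstream_flank | downstream_flank | outside
    overlap_bp: int


def _flank_intervals(te: TECopy, flank_bp: int):
    """(upstream, downstream) flank intervals in genome coordinates.

    Up/downstream follow the element's strand; flanks are not clipped at
    neighbouring TE bodies (zone precedence resolves overlaps).
    """
    left = (max(0, te.start - flank_bp), te.start)
    right = (te.end, te.end + flank_bp)
    if te.strand == "-":
        return right, left
    return left, right


def assign_ssrs_to_tes(ssrs: list[SSRRecord], tes: list[TECopy],
                       flank_bp: int = DEFAULT_FLANK_BP
                       ) -> list[TESSRAssignment]:
    """Assign every SSR to exactly one zone.

    Zone precedence: inside > flank > outside.  Any >=1 bp overlap with
    a TE body is "inside".  Among multiple candidate TEs the one with
    the largest overlap wins; ties go to the TE whose start is nearest
    the SSR, then to the leftmost TE.
    """
    body = {}
    flank = {}
    for idx, te in enumerate(tes):
        body.setdefault(te.seq_id, IntervalTree()).addi(
            te.start, max(te.end, te.start + 1), idx)
        up, down = _flank_intervals(te, flank_bp)
        for zone, (s, e) in (("upstream_flank", up), ("downstream_flank", down)):
            if e > s:
                flank.setdefault(te.seq_id, IntervalTree()).addi(
                    s, e, (idx, zone))

    def pick(hits):
        # hits: list of (overlap, te_index, zone); deterministic choice
        def key(h):
            te = tes[h[1]]
            return (-h[0], abs((ssr.start + ssr.end) / 2 - te.start),
                    te.start, h[1])
        return min(hits, key=key)

    out = []
    for ssr in ssrs:
        hits = []
        for iv in body.get(ssr.seq_id, IntervalTree()).overlap(ssr.start,
                                                               ssr.end):
            ov = min(ssr.end, iv.end) - max(ssr.start, iv.begin)
            if ov >= 1:
                hits.append((ov, iv.data, "inside"))
        if not hits:
            for iv in flank.get(ssr.seq_id, IntervalTree()).overlap(
                    ssr.start, ssr.end):
                ov = min(ssr.end, iv.end) - max(ssr.start, iv.begin)
                if ov >= 1:
                    hits.append((ov, iv.data[0], iv.data[1]))
        if hits:
            ov, idx, zone = pick(hits)
            out.append(TESSRAssignment(ssr, tes[idx], zone, ov))
        else:
            out.append(TESSRAssignment(ssr, None, "outside", 0))
    return out


def family_summary(assignments: list[TESSRAssignment], tes: list[TECopy],
                   include_flanks: bool = True) -> pd.DataFrame:
    """Per (family, epoch) SSR-harboring summary.

    harboring_fraction counts copies with >=1 SSR inside the body (and
    in the flanks when *include_flanks*); harboring_fraction_inside is
    always body-only.  ssr_density is SSRs per Mb of family sequence;
    ssr_in_zone_fraction is the share of all SSRs assigned to this
    (family, epoch) inside/flank.
    """
    te_index = {id(te): i for i, te in enumerate(tes)}
    inside_hit = np.zeros(len(tes), bool)
    any_hit = np.zeros(len(tes), bool)
    n_ssr = np.zeros(len(tes), int)
    total = len(assignments)
    for a in assignments:
        if a.te is None:
            continue
        i = te_index[id(a.te)]
        if a.zone == "inside":
            inside_hit[i] = True
            any_hit[i] = True
            n_ssr[i] += 1
        elif include_flanks:
            any_hit[i] = True
            n_ssr[i] += 1
    df = pd.DataFrame({
        "family": [t.family for t in tes],
        "epoch": [t.epoch for t in tes],
        "length": [t.length for t in tes],
        "inside": inside_hit,
        "any": any_hit,
        "n_ssr": n_ssr,
    })
    g = df.groupby(["family", "epoch"])
    out = pd.DataFrame({
        "n_copies": g.size(),
        "n_harboring": g["any"].sum(),
        "n_harboring_inside": g["inside"].sum(),
        "family_bp": g["length"].sum(),
        "n_ssr": g["n_ssr"].sum(),
    })
    out["harboring_fraction"] = out["n_harboring"] / out["n_copies"]
    out["harboring_fraction_inside"] = (
        out["n_harboring_inside"] / out["n_copies"])
    out["ssr_density"] = out["n_ssr"] / (out["family_bp"] / 1e6)
    out["ssr_in_zone_fraction"] = out["n_ssr"] / total if total else np.nan
    return out.reset_index()


def epoch_ssr_share(assignments: list[TESSRAssignment]) -> pd.Series:
    """Fraction of all SSRs lying inside or in the flanks of TEs of each
    epoch (the statistic behind 'ancient TEs comprise X% of SSRs')."""
    total = len(assignments)
    counts: dict[str, int] = {}
    for a in assignments:
        if a.te is not None and a.zone != "outside":
            counts[a.te.epoch] = counts.get(a.te.epoch, 0) + 1
    return pd.Series(counts, dtype=float) / total if total else pd.Series(
        dtype=float)


def family_density_ratio(summary_a: pd.DataFrame, summary_b: pd.DataFrame
                         ) -> pd.DataFrame:
    """Per-family log2 SSR-density ratio between two genomes.

    Positive values mean higher SSR density in genome A's copies of the
    family.  Count-based chi-square significance with BH adjustment;
    zero density on one side yields a +/-inf sentinel and a flag.
    """
    a = summary_a.groupby("family")[["n_ssr", "family_bp"]].sum()
    b = summary_b.groupby("family")[["n_ssr", "family_bp"]].sum()
    fams = sorted(set(a.index) | set(b.index))
    rows = []
    for fam in fams:
        na, ba = (int(a["n_ssr"].get(fam, 0)), int(a["family_bp"].get(fam, 0)))
        nb, bb = (int(b["n_ssr"].get(fam, 0)), int(b["family_bp"].get(fam, 0)))
        da = na / (ba / 1e6) if ba else np.nan
        db = nb / (bb / 1e6) if bb else np.nan
        if da and db:
            ratio, flag = float(np.log2(da / db)), ""
        elif np.isnan(da) or np.isnan(db):
            ratio, flag = np.nan, "missing_family"
        else:
            ratio = np.inf if da else -np.inf
            flag = "zero_density"
        if ba and bb and na + nb > 0:
            tbl = np.array([[na, max(ba - na, 1)], [nb, max(bb - nb, 1)]])
            p = float(stats.chi2_contingency(tbl, correction=False)[1])
        else:
            p = np.nan
        rows.append((fam, da, db, ratio, p, flag))
    out = pd.DataFrame(rows, columns=[
        "family", "density_a", "density_b", "log2_density_ratio", "pvalue",
        "flag"]).set_index("family")
    mask = out["pvalue"].notna()
    out["padj"] = np.nan
    if mask.any():
        out.loc[mask, "padj"] = multipletests(
            out.loc[mask, "pvalue"], method="fdr_bh")[1]
    return out
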