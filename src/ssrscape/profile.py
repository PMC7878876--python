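"""Genome-wide SSR profiles and between-genome comparisons.

A profile summarises detected SSRs per canonical motif class (and per
period class): count, density per Mb, mean/total/max length and genome
fraction.  Profiles of different genomes are compared class-by-class
with two-proportion chi-square tests on counts versus genome lengths,
Benjamini-Hochberg adjusted, and summarised jointly by a PCA of the
per-class density composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests

from .detect import SSRRecord


@dataclass
class GenomeSSRProfile:
    """Per-motif-class SSR summary statistics for one genome."""

    genome_id: str
    genome_length: int
    per_class: pd.DataFrame    # index: motif class; columns below
    per_period: pd.DataFrame   # index: period 1..6
    total_count: int = 0
    total_bp: int = 0

    COLUMNS = ("count", "density", "mean_length", "total_bp",
               "genome_fraction", "max_length")

    @property
    def total_density(self) -> float:
        return self.total_count / (self.genome_length / 1e6)

    @property
    def total_fraction(self) -> float:
        return self.total_bp / self.genome_length

    def to_frame(self) -> pd.DataFrame:
        return self.per_class.copy()


def _summarise(df: pd.DataFrame, by: str, genome_length: int) -> pd.DataFrame:
    g = df.groupby(by)["length"]
    out = pd.DataFrame({
        "count": g.size(),
        "mean_length": g.mean(),
        "total_bp": g.sum(),
        "max_length": g.max(),
    })
    out["density"] = out["count"] / (genome_length / 1e6)
    out["genome_fraction"] = out["total_bp"] / genome_length
    return out[list(GenomeSSRProfile.COLUMNS)]


def profile(ssrs: list[SSRRecord], genome_length: int,
            genome_id: str = "genome") -> GenomeSSRProfile:
    """Build a :class:`GenomeSSRProfile` from detected records.

    Empty classes simply do not appear; mean_length is therefore never
    reported as 0 for a class with no records.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be > 0")
    if not ssrs:
        empty = pd.DataFrame(columns=list(GenomeSSRProfile.COLUMNS))
        return GenomeSSRProfile(genome_id, genome_length, empty,
                                empty.copy(), 0, 0)
    df = pd.DataFrame({
        "motif": [r.motif for r in ssrs],
        "period": [r.period for r in ssrs],
        "length": [r.length for r in ssrs],
    })
    per_class = _summarise(df, "motif", genome_length)
    per_period = _summarise(df, "period", genome_length)
    return GenomeSSRProfile(genome_id, genome_length, per_class, per_period,
                            int(df.shape[0]), int(df["length"].sum()))


@dataclass
class ProfileComparison:
    """Class-wise comparison of two genome profiles."""

    genome_a: str
    genome_b: str
    table: pd.DataFrame = field(repr=False)
    # columns: count_a, count_b, density_a, density_b, log2_density_ratio,
    #          log2_length_ratio, pvalue, padj, only_in


def compare_profiles(a: GenomeSSRProfile, b: GenomeSSRProfile,
                     ) -> ProfileComparison:
    """Compare per-class SSR density and length between two genomes.

    log2 ratios of density (a/b) and mean length; significance of the
    count difference by a chi-square two-proportion test of counts
    against genome lengths; BH adjustment across classes.  A class
    present in only one genome gets a +/-inf ratio and an ``only_in``
    flag; classes absent from both are skipped.
    """
    classes = sorted(set(a.per_class.index) | set(b.per_class.index))
    rows = []
    for cls in classes:
        ca = int(a.per_class["count"].get(cls, 0))
        cb = int(b.per_class["count"].get(cls, 0))
        da = ca / (a.genome_length / 1e6)
        db = cb / (b.genome_length / 1e6)
        la = a.per_class["mean_length"].get(cls, np.nan)
        lb = b.per_class["mean_length"].get(cls, np.nan)
        if da > 0 and db > 0:
            ratio = float(np.log2(da / db))
            only = ""
        else:
            ratio = np.inf if da > 0 else -np.inf
            only = a.genome_id if da > 0 else b.genome_id
        lratio = float(np.log2(la / lb)) if la > 0 and lb > 0 else np.nan
        # two-proportion test: counts vs per-bp opportunity
        tbl = np.array([[ca, a.genome_length - ca],
                        [cb, b.genome_length - cb]])
        if ca + cb > 0:
            p = float(stats.chi2_contingency(tbl, correction=False)[1])
        else:
            p = np.nan
        rows.append((cls, ca, cb, da, db, ratio, lratio, p, only))
    table = pd.DataFrame(rows, columns=[
        "motif", "count_a", "count_b", "density_a", "density_b",
        "log2_density_ratio", "log2_length_ratio", "pvalue", "only_in",
    ]).set_index("motif")
    mask = table["pvalue"].notna()
    table["padj"] = np.nan
    if mask.any():
        table.loc[mask, "padj"] = multipletests(
            table.loc[mask, "pvalue"], method="fdr_bh")[1]
    return ProfileComparison(a.genome_id, b.genome_id, table)


def composition_pca(profiles: list[GenomeSSRProfile],
                    n_components: int = 2) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PCA of per-class SSR density composition across genomes.

    Feature vector per genome: standardized per-class density over the
    union of motif classes (missing classes are 0).  The sign of each
    component is fixed so that its largest-magnitude loading is
    positive.  Returns (scores, loadings).
    """
    if len(profiles) < 3:
        raise ValueError("composition_pca needs at least 3 profiles")
    classes = sorted(set().union(*(set(p.per_class.index) for p in profiles)))
    X = np.zeros((len(profiles), len(classes)))
    for i, p in enumerate(profiles):
        dens = p.per_class["density"]
        for j, cls in enumerate(classes):
            X[i, j] = dens.get(cls, 0.0)
    scaler = StandardScaler()
    with np.errstate(invalid="ignore", divide="ignore"):
        Xs = scaler.fit_transform(X)
    Xs = np.nan_to_num(Xs)
    n_components = min(n_components, len(profiles) - 1, len(classes))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Xs)
    loadings = pca.components_
    for k in range(loadings.shape[0]):
        if loadings[k, np.argmax(np.abs(loadings[k]))] < 0:
            loadings[k] *= -1
            scores[:, k] *= -1
    cols = [f"PC{k + 1}" for k in range(n_components)]
    score_df = pd.DataFrame(scores, columns=cols,
                            index=[p.genome_id for p in profiles])
    score_df.index.name = "genome"
    loading_df = pd.DataFrame(loadings.T, columns=cols, index=classes)
    loading_df.index.name = "motif"
    return score_df, loading_df
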