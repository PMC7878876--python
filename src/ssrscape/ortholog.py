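"""Ortholog-level SSR composition comparison.

SSRs are mapped to gene features (UTRs, CDS, introns) of one
representative transcript per gene, matched between orthologous gene
pairs by (feature type, ordinal, motif class) — e.g. "the (AG)n in
intron 5" — and classified as conserved, elongated/contracted (repeat
ratio above a fold threshold) or inserted on one side.  Matching by
feature ordinal rather than positional alignment is robust to the poor
intergenic synteny of highly rearranged genomes.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import SSRRecord

FEATURE_TYPES = ("five_prime_UTR", "exon", "CDS", "intron",
                 "three_prime_UTR")
#: features eligible for SSR assignment, in tie-break precedence order
ASSIGN_PRECEDENCE = ("CDS", "five_prime_UTR", "three_prime_UTR", "intron",
                     "exon")
DEFAULT_MIN_RATIO = 2.0


@dataclass
class GeneModel:
    """One gene with the features of its representative transcript.

    features: list of (type, start, end, ordinal); ordinals count from
    the gene's 5' end following strand.  Introns are derived from exon
    gaps when not annotated.
    """

    gene_id: str
    seq_id: str
    strand: str
    start: int
    end: int
    features: list[tuple[str, int, int, int]]


def _add_ordinals(feats: list[tuple[str, int, int]], strand: str
                  ) -> list[tuple[str, int, int, int]]:
    by_type: dict[str, list[tuple[str, int, int]]] = defaultdict(list)
    for f in feats:
        by_type[f[0]].append(f)
    out = []
    for ftype, items in by_type.items():
        items.sort(key=lambda f: f[1], reverse=(strand == "-"))
        for k, (t, s, e) in enumerate(items, start=1):
            out.append((t, s, e, k))
    out.sort(key=lambda f: f[1])
    return out


def gene_models_from_gff(gff: pd.DataFrame) -> list[GeneModel]:
    """Build one GeneModel per gene from a flat GFF3 frame.

    The representative transcript is the one with the longest total CDS
    (total exon length as fallback); introns are the gaps between its
    exons.  Genes whose features all have zero length are skipped.
    """
    genes = gff[gff["type"] == "gene"]
    mrnas = gff[gff["type"].isin(["mRNA", "transcript"])]
    parts = gff[gff["type"].isin(FEATURE_TYPES)]
    parts_by_parent: dict[str, list] = defaultdict(list)
    for row in parts.itertuples():
        parts_by_parent[row.parent].append(row)
    models = []
    for g in genes.itertuples():
        children = mrnas[mrnas["parent"] == g.id]
        tx_ids = list(children["id"]) if len(children) else [g.id]
        best, best_len = None, -1
        for tx in tx_ids:
            feats = parts_by_parent.get(tx, [])
            cds_len = sum(r.end - r.start for r in feats if r.type == "CDS")
            exon_len = sum(r.end - r.start for r in feats if r.type == "exon")
            score = cds_len if cds_len else exon_len
            if score > best_len:
                best, best_len = feats, score
        if not best or best_len <= 0:
            continue
        feats = [(r.type, r.start, r.end) for r in best
                 if r.end > r.start]
        exons = sorted([f for f in feats if f[0] == "exon"],
                       key=lambda f: f[1])
        if not any(f[0] == "intron" for f in feats):
            for (_, _, e0), (_, s1, _) in zip(exons, exons[1:]):
                if s1 > e0:
                    feats.append(("intron", e0, s1))
        models.append(GeneModel(
            gene_id=g.id, seq_id=g.seq_id, strand=g.strand,
            start=g.start, end=g.end,
            features=_add_ordinals(feats, g.strand)))
    return models


def gene_models_to_gff_frame(models: list[GeneModel]) -> pd.DataFrame:
    """Gene models as a flat GFF3 frame (gene + mRNA + feature rows)
    suitable for :func:`ssrscape.io.write_gff3`."""
    rows = []
    for gm in models:
        tx = gm.gene_id + ".t1"
        rows.append((gm.seq_id, "gene", gm.start, gm.end, gm.strand,
                     gm.gene_id, "", f"ID={gm.gene_id}"))
        rows.append((gm.seq_id, "mRNA", gm.start, gm.end, gm.strand,
                     tx, gm.gene_id, f"ID={tx};Parent={gm.gene_id}"))
        for ftype, s, e, _ in gm.features:
            rows.append((gm.seq_id, ftype, s, e, gm.strand, "", tx,
                         f"Parent={tx}"))
    return pd.DataFrame(rows, columns=[
        "seq_id", "type", "start", "end", "strand", "id", "parent",
        "attrs"])


def map_ssrs_to_features(ssrs: list[SSRRecord], genes: list[GeneModel]
                         ) -> dict:
    """Per-gene SSR inventory.

    Each SSR overlapping a gene body is assigned to the overlapping
    feature with the largest overlap (precedence order breaks ties);
    exons only catch SSRs not covered by CDS/UTR sub-features.  Returns
    {"inventory": {gene_id: [(feature, ordinal, SSRRecord), ...]},
    "n_genes": int, "n_genes_with_ssr": int, "fraction_with_ssr": float}.
    """
    by_seq: dict[str, list[GeneModel]] = defaultdict(list)
    for gm in genes:
        by_seq[gm.seq_id].append(gm)
    for lst in by_seq.values():
        lst.sort(key=lambda g: g.start)
    prec = {t: i for i, t in enumerate(ASSIGN_PRECEDENCE)}
    inventory: dict[str, list] = {gm.gene_id: [] for gm in genes}
    for ssr in sorted(ssrs, key=lambda r: (r.seq_id, r.start)):
        candidates = []
        for gm in by_seq.get(ssr.seq_id, []):
            if gm.start >= ssr.end:
                break
            if gm.end <= ssr.start:
                continue
            for ftype, fs, fe, ordinal in gm.features:
                ov = min(ssr.end, fe) - max(ssr.start, fs)
                if ov > 0:
                    candidates.append((ov, prec.get(ftype, 99), gm.gene_id,
                                       ftype, ordinal))
        if not candidates:
            continue
        # drop exon hits when a sub-feature of the same gene also hits
        non_exon_genes = {c[2] for c in candidates if c[3] != "exon"}
        candidates = [c for c in candidates
                      if c[3] != "exon" or c[2] not in non_exon_genes]
        ov, _, gene_id, ftype, ordinal = max(
            candidates, key=lambda c: (c[0], -c[1]))
        inventory[gene_id].append((ftype, ordinal, ssr))
    n_with = sum(1 for v in inventory.values() if v)
    return {"inventory": inventory, "n_genes": len(genes),
            "n_genes_with_ssr": n_with,
            "fraction_with_ssr": n_with / len(genes) if genes else np.nan}


@dataclass
class GeneSSREvent:
    """Classification of one SSR position across an ortholog pair.

    event orientation is relative to genome B: "elongated" means the
    repeat is at least min_ratio-fold longer in B, "contracted" at
    least min_ratio-fold shorter in B.
    """

    pair_id: str
    gene_id_a: str
    gene_id_b: str
    feature_type: str
    ordinal: int
    motif: str
    repeats_a: float   # NaN when absent
    repeats_b: float
    event: str         # conserved | elongated | contracted | inserted_a | inserted_b
    elongation_ratio: float  # max/min repeats when both present, else NaN


def match_ortholog_ssrs(inventory_a: dict, inventory_b: dict,
                        ortholog_pairs: pd.DataFrame,
                        min_ratio: float = DEFAULT_MIN_RATIO
                        ) -> tuple[list[GeneSSREvent], int]:
    """Match SSRs within ortholog pairs and classify events.

    SSRs are grouped by (feature type, ordinal, motif class) and matched
    greedily in rank order along the gene; unmatched SSRs become
    inserted_a/inserted_b events.  Pairs missing a gene model on either
    side are skipped and counted (second return value).
    """
    inv_a = inventory_a["inventory"]
    inv_b = inventory_b["inventory"]
    events: list[GeneSSREvent] = []
    skipped = 0
    for row in ortholog_pairs.itertuples():
        ga, gb = row.gene_id_a, row.gene_id_b
        if ga not in inv_a or gb not in inv_b:
            skipped += 1
            continue
        pair_id = f"{ga}|{gb}"
        keyed_a: dict[tuple, list[SSRRecord]] = defaultdict(list)
        keyed_b: dict[tuple, list[SSRRecord]] = defaultdict(list)
        for ftype, ordinal, ssr in inv_a[ga]:
            keyed_a[(ftype, ordinal, ssr.motif)].append(ssr)
        for ftype, ordinal, ssr in inv_b[gb]:
            keyed_b[(ftype, ordinal, ssr.motif)].append(ssr)
        for key in sorted(set(keyed_a) | set(keyed_b)):
            ftype, ordinal, motif = key
            sa = sorted(keyed_a.get(key, []), key=lambda r: r.start)
            sb = sorted(keyed_b.get(key, []), key=lambda r: r.start)
            for ra, rb in zip(sa, sb):
                ratio = max(ra.repeats, rb.repeats) / min(ra.repeats,
                                                          rb.repeats)
                if ratio >= min_ratio:
                    event = "elongated" if rb.repeats > ra.repeats \
                        else "contracted"
                else:
                    event = "conserved"
                events.append(GeneSSREvent(
                    pair_id, ga, gb, ftype, ordinal, motif,
                    ra.repeats, rb.repeats, event, ratio))
            for ra in sa[len(sb):]:
                events.append(GeneSSREvent(
                    pair_id, ga, gb, ftype, ordinal, motif,
                    ra.repeats, np.nan, "inserted_a", np.nan))
            for rb in sb[len(sa):]:
                events.append(GeneSSREvent(
                    pair_id, ga, gb, ftype, ordinal, motif,
                    np.nan, rb.repeats, "inserted_b", np.nan))
    return events, skipped


def event_summary(events: list[GeneSSREvent], top_n: int = 10) -> dict:
    """Counts per event class and per feature type, plus the most
    extreme elongation/contraction events by repeat ratio."""
    if not events:
        zero = pd.Series(dtype=int)
        return {"by_event": zero, "by_feature": pd.DataFrame(),
                "extreme": []}
    df = pd.DataFrame({
        "event": [e.event for e in events],
        "feature_type": [e.feature_type for e in events],
        "ratio": [e.elongation_ratio for e in events],
    })
    by_event = df["event"].value_counts()
    by_feature = df.groupby(["feature_type", "event"]).size().unstack(
        fill_value=0)
    with_ratio = [e for e in events if not np.isnan(e.elongation_ratio)]
    extreme = sorted(with_ratio, key=lambda e: -e.elongation_ratio)[:top_n]
    return {"by_event": by_event, "by_feature": by_feature,
            "extreme": extreme}
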