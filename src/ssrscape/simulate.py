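"""Synthetic genomes with planted SSRs, TEs, genes, rearrangements and
peaks, plus an exhaustive ground-truth ledger.

The generator emulates the statistical structure of an SSR-rich shrimp-
like genome: TE copies mutated from family consensus sequences at
controlled divergence (ancient DNA transposons vs recently transposed
retroelements), SSRs planted inside TE copies, in their 100 bp flanks
and in background sequence with unimodal or bimodal (lognormal-mixture)
length distributions, gene models whose introns and UTRs carry SSRs,
two descendant genomes with lineage-specific SSR elongation/insertion,
discordant read pairs emitted around planted breakpoints, and
accessibility peaks whose SSR overlap probability rises with
differential significance.  Every planted element is recorded in a
:class:`SyntheticTruth`, and the same seed reproduces every output
byte.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .detect import SSRRecord
from .motifs import canonical_motif
from .ortholog import GeneModel, _add_ordinals
from .te import TECopy, classify_epoch, te_age, DEFAULT_SUBSTITUTION_RATE

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ------------------------------------------------------------- configs

@dataclass
class LengthMixture:
    """Lognormal (mixture) SSR length distribution, in bp.

    medians/sigmas/weights describe one component per entry; sigma is
    the standard deviation of log10(length).
    """

    medians: tuple = (30.0,)
    sigmas: tuple = (0.15,)
    weights: tuple = (1.0,)

    def sample(self, n: int, rng: np.random.Generator,
               min_len: int = 12) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n,
                          p=np.asarray(self.weights)
                          / np.sum(self.weights))
        med = np.asarray(self.medians)[comp]
        sig = np.asarray(self.sigmas)[comp]
        lengths = 10 ** (np.log10(med) + sig * rng.standard_normal(n))
        return np.maximum(np.round(lengths).astype(int), min_len)


@dataclass
class SSRClassSpec:
    motif: str
    rate_per_mb: float
    lengths: LengthMixture = field(default_factory=LengthMixture)


@dataclass
class TEFamilySpec:
    name: str
    te_class: str
    consensus_length: int
    copy_number: int
    divergence: float          # target substitutions/site vs consensus
    ssr_carriage: float        # P(copy carries an SSR inside the body)
    flank_carriage: float = 0.0  # P(an SSR sits in the 100 bp flank)
    motif_mix: dict[str, float] = field(
        default_factory=lambda: {"AC": 0.5, "AG": 0.5})
    carried_lengths: LengthMixture = field(default_factory=LengthMixture)


@dataclass
class GeneSpec:
    n_genes: int = 40
    n_exons: int = 5
    exon_len: int = 200
    intron_len: int = 400
    utr_len: int = 200
    intron_ssr_per_gene: float = 1.0   # expected SSRs over a gene's introns
    utr_ssr_per_gene: float = 0.3
    motif_mix: dict[str, float] = field(
        default_factory=lambda: {"AG": 0.5, "AT": 0.25, "AAT": 0.25})
    ssr_lengths: LengthMixture = field(
        default_factory=lambda: LengthMixture((40.0,), (0.2,), (1.0,)))
    minus_strand_fraction: float = 0.25


@dataclass
class ReadPairSpec:
    insert_mean: float = 170.0
    insert_sd: float = 20.0
    read_length: int = 50
    coverage: float = 30.0        # physical pair coverage, x
    chimera_rate: float = 5e-5    # fraction of pairs with random mates
    min_mapq: int = 60            # emitted mapq placeholder


@dataclass
class RearrangementSpec:
    n_breakpoints: int = 10
    ssr_bias_bp: tuple | None = None   # (min,max) distance to an SSR block
    pair_spec: ReadPairSpec = field(default_factory=ReadPairSpec)


@dataclass
class PeakSpec:
    n_all: int = 2000
    n_diff: int = 600
    width_mean: float = 400.0
    width_sd: float = 100.0
    base_overlap_prob: float = 0.05
    # SSR-overlap probability per differential stratum, loosest->strictest
    stratum_overlap_probs: tuple = (0.15, 0.3, 0.5)
    thresholds: tuple = (1e-3, 1e-5, 1e-10)


@dataclass
class LineageEvents:
    """Divergence events applied to one descendant lineage."""

    elongate_motif: str | None = None
    elongate_factor: float = 1.0
    extra_motif: str | None = None        # extra background planting
    extra_rate_per_mb: float = 0.0
    extra_lengths: LengthMixture = field(default_factory=LengthMixture)
    intron_insertion_per_gene: float = 0.0
    ssr_deletion_prob: float = 0.0
    substitution_rate: float = 0.01       # neutral divergence of bg/TE


def default_te_families() -> list[TEFamilySpec]:
    """Four families echoing the shrimp TE landscape: an ancient,
    heavily SSR-loaded DNA transposon and three recent retroelements."""
    bimodal_at = LengthMixture((25.0, 120.0), (0.12, 0.12), (0.7, 0.3))
    return [
        TEFamilySpec("En-Spm", "DNA", 600, 800, 0.21, 0.9, 0.1,
                     {"AC": 0.4, "AG": 0.4, "A": 0.2}),
        TEFamilySpec("Penelope", "LINE", 500, 400, 0.02, 0.5, 0.1,
                     {"AT": 1.0}, bimodal_at),
        TEFamilySpec("RTE-BovB", "LINE", 500, 300, 0.03, 0.5, 0.1,
                     {"AC": 0.5, "AG": 0.5}),
        TEFamilySpec("Gypsy", "LTR", 700, 300, 0.05, 0.5, 0.1,
                     {"AAT": 1.0}),
    ]


def default_background_ssrs() -> list[SSRClassSpec]:
    """Shrimp-like background: dominant dinucleotides with bimodal
    lengths, plus A-rich and telomeric classes."""
    bi = LengthMixture((25.0, 120.0), (0.12, 0.12), (0.7, 0.3))
    uni = LengthMixture((30.0,), (0.15,), (1.0,))
    return [
        SSRClassSpec("AT", 3000.0, bi),
        SSRClassSpec("AC", 80.0, bi),
        SSRClassSpec("AG", 80.0, bi),
        SSRClassSpec("A", 100.0, uni),
        SSRClassSpec("AAT", 160.0, uni),
        SSRClassSpec("AACCT", 20.0, LengthMixture((40.0,), (0.2,), (1.0,))),
    ]


@dataclass
class SimConfig:
    seed: int = 0
    genome_length: int = 5_000_000
    gc: float = 0.36
    seq_id: str = "chr1"
    te_families: list[TEFamilySpec] = field(
        default_factory=default_te_families)
    background_ssrs: list[SSRClassSpec] = field(
        default_factory=default_background_ssrs)
    genes: GeneSpec = field(default_factory=GeneSpec)
    rearrangement: RearrangementSpec = field(
        default_factory=RearrangementSpec)
    peaks: PeakSpec = field(default_factory=PeakSpec)
    flank_gap_max: int = 100
    min_background_gap: int = 20
    substitution_rate: float = DEFAULT_SUBSTITUTION_RATE
    # epoch split for truth labels; 50 Myr cleanly separates the ancient
    # family (~105 Myr) from the recent ones (10-25 Myr) despite
    # per-copy binomial divergence noise
    split_time: float = 50e6


@dataclass
class SyntheticTruth:
    """Exhaustive ledger of everything planted in one genome."""

    genome_length: int
    ssrs: list[SSRRecord] = field(default_factory=list)
    tes: list[TECopy] = field(default_factory=list)
    te_carriage: list[dict] = field(default_factory=list)  # per TE copy
    genes: list[GeneModel] = field(default_factory=list)
    breakpoints: list[tuple] = field(default_factory=list)
    peak_truth: pd.DataFrame | None = None
    events: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "genome_length": self.genome_length,
            "ssrs": [asdict(r) for r in self.ssrs],
            "tes": [asdict(t) for t in self.tes],
            "te_carriage": self.te_carriage,
            "genes": [{"gene_id": g.gene_id, "seq_id": g.seq_id,
                       "strand": g.strand, "start": g.start, "end": g.end,
                       "features": g.features} for g in self.genes],
            "breakpoints": self.breakpoints,
            "events": self.events,
        }
        if self.peak_truth is not None:
            payload["peak_truth"] = self.peak_truth.to_dict("records")
        Path(path).write_text(json.dumps(payload))


# -------------------------------------------------------------- tokens

@dataclass
class _Token:
    kind: str                 # bg | ssr | te
    seq: str = ""
    motif: str = ""
    length: int = 0
    meta: dict = field(default_factory=dict)

    def materialize(self) -> str:
        if self.kind == "ssr":
            unit = self.motif
            return (unit * math.ceil(self.length / len(unit)))[:self.length]
        return self.seq

    def size(self) -> int:
        return self.length if self.kind == "ssr" else len(self.seq)


def _random_seq(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode()


def _mutate(seq: str, rate: float, rng: np.random.Generator
            ) -> tuple[str, float]:
    """Substitute each site with probability *rate* (to a different
    base); returns (sequence, realized substitution fraction)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    n_hit = int(hit.sum())
    if n_hit:
        shift = rng.integers(1, 4, size=n_hit)
        idx = {65: 0, 67: 1, 71: 2, 84: 3}
        base_idx = np.array([idx[b] for b in arr[hit]])
        arr[hit] = _BASES[(base_idx + shift) % 4]
    return arr.tobytes().decode(), n_hit / max(arr.size, 1)


def _pick_motif(mix: dict[str, float], rng: np.random.Generator) -> str:
    motifs = sorted(mix)
    w = np.array([mix[m] for m in motifs], dtype=float)
    return motifs[rng.choice(len(motifs), p=w / w.sum())]


def _ssr_token(motif: str, length: int, **meta) -> _Token:
    length = max(int(length), 2 * len(motif))
    return _Token("ssr", motif=motif, length=length, meta=meta)


def _build_te_group(fam: TEFamilySpec, copy_id: int, cfg: SimConfig,
                    rng: np.random.Generator, consensus: str) -> list[_Token]:
    body, div = _mutate(consensus, fam.divergence, rng)
    carried = rng.random() < fam.ssr_carriage
    meta = {"te_id": f"{fam.name}.{copy_id}", "family": fam.name,
            "te_class": fam.te_class, "divergence": div, "carried": carried}
    tokens: list[_Token] = []
    if carried:
        motif = _pick_motif(fam.motif_mix, rng)
        length = int(fam.carried_lengths.sample(1, rng)[0])
        cut = int(rng.integers(10, len(body) - 10))
        tokens += [
            _Token("te", seq=body[:cut], meta=meta),
            _ssr_token(motif, length, zone="inside", **meta),
            _Token("te", seq=body[cut:], meta=meta),
        ]
    else:
        tokens.append(_Token("te", seq=body, meta=meta))
    if rng.random() < fam.flank_carriage:
        gap = int(rng.integers(5, cfg.flank_gap_max - 40))
        motif = _pick_motif(fam.motif_mix, rng)
        length = int(fam.carried_lengths.sample(1, rng)[0])
        tokens += [
            _Token("bg", seq=_random_seq(gap, cfg.gc, rng)),
            _ssr_token(motif, length, zone="flank", **meta),
        ]
    return tokens


def _build_gene_group(spec: GeneSpec, gene_id: str, cfg: SimConfig,
                      rng: np.random.Generator) -> list[_Token]:
    strand = "-" if rng.random() < spec.minus_strand_fraction else "+"

    def bg(n, **meta):
        return _Token("bg", seq=_random_seq(n, cfg.gc, rng), meta=meta)

    gmeta = {"gene_id": gene_id, "strand": strand}
    feats: list[list[_Token]] = []  # logical 5'->3' feature order
    utr_ssr = rng.random() < spec.utr_ssr_per_gene
    first = [bg(spec.utr_len, feature="five_prime_UTR", ordinal=1, **gmeta)]
    if utr_ssr:
        motif = _pick_motif(spec.motif_mix, rng)
        first.append(_ssr_token(
            motif, int(spec.ssr_lengths.sample(1, rng)[0]),
            feature="five_prime_UTR", ordinal=1, **gmeta))
        first.append(bg(30, feature="five_prime_UTR", ordinal=1, **gmeta))
    feats.append(first)
    n_intron_ssr = rng.poisson(spec.intron_ssr_per_gene)
    ssr_introns = rng.integers(1, spec.n_exons, size=n_intron_ssr) \
        if spec.n_exons > 1 else np.array([], dtype=int)
    for k in range(1, spec.n_exons + 1):
        feats.append([bg(spec.exon_len, feature="exon", ordinal=k, **gmeta)])
        if k < spec.n_exons:
            intron = [bg(spec.intron_len // 2, feature="intron", ordinal=k,
                         **gmeta)]
            for _ in range(int((ssr_introns == k).sum())):
                motif = _pick_motif(spec.motif_mix, rng)
                intron.append(_ssr_token(
                    motif, int(spec.ssr_lengths.sample(1, rng)[0]),
                    feature="intron", ordinal=k, **gmeta))
                intron.append(bg(30, feature="intron", ordinal=k, **gmeta))
            intron.append(bg(spec.intron_len // 2, feature="intron",
                             ordinal=k, **gmeta))
            feats.append(intron)
    feats.append([bg(spec.utr_len, feature="three_prime_UTR", ordinal=1,
                     **gmeta)])
    if strand == "-":
        feats = feats[::-1]
    return [t for group in feats for t in group]


def build_tokens(cfg: SimConfig, rng: np.random.Generator) -> list[_Token]:
    """Assemble the token list of one genome (elements interleaved with
    background gaps).  Raises if planting exceeds genome capacity."""
    from .detect import find_ssrs

    groups: list[list[_Token]] = []
    for fam in cfg.te_families:
        # a chance repeat in the consensus would be inherited by every
        # copy and bias harboring rates; resample until clean
        for _ in range(100):
            consensus = _random_seq(fam.consensus_length, cfg.gc, rng)
            if not find_ssrs(consensus):
                break
        for i in range(fam.copy_number):
            groups.append(_build_te_group(fam, i, cfg, rng, consensus))
    for spec in cfg.background_ssrs:
        n = rng.poisson(spec.rate_per_mb * cfg.genome_length / 1e6)
        lengths = spec.lengths.sample(n, rng)
        for ln in lengths:
            groups.append([_ssr_token(spec.motif, int(ln), zone="background")])
    for gi in range(cfg.genes.n_genes):
        groups.append(_build_gene_group(cfg.genes, f"g{gi + 1}", cfg, rng))
    rng.shuffle(groups)
    used = sum(t.size() for g in groups for t in g)
    n_gaps = len(groups) + 1
    fill = cfg.genome_length - used - n_gaps * cfg.min_background_gap
    if fill < 0:
        raise ValueError(
            f"planting density exceeds genome capacity: {used} planted bp "
            f"+ minimum gaps > genome_length {cfg.genome_length}")
    extra = rng.multinomial(fill, np.full(n_gaps, 1.0 / n_gaps))
    tokens: list[_Token] = []
    for i, g in enumerate(groups):
        tokens.append(_Token("bg", seq=_random_seq(
            cfg.min_background_gap + int(extra[i]), cfg.gc, rng)))
        tokens.extend(g)
    tokens.append(_Token("bg", seq=_random_seq(
        cfg.min_background_gap + int(extra[-1]), cfg.gc, rng)))
    return tokens


def materialize(tokens: list[_Token], cfg: SimConfig
                ) -> tuple[dict[str, str], SyntheticTruth]:
    """Turn a token list into (sequences, truth ledger)."""
    seq_id = cfg.seq_id
    pieces: list[str] = []
    pos = 0
    ssrs: list[SSRRecord] = []
    te_spans: dict[str, list] = {}
    te_meta: dict[str, dict] = {}
    te_order: list[str] = []
    te_ssrs: dict[str, list] = {}
    gene_feats: dict[str, list] = {}
    gene_strand: dict[str, str] = {}
    for tok in tokens:
        piece = tok.materialize()
        start, end = pos, pos + len(piece)
        pieces.append(piece)
        pos = end
        meta = tok.meta
        if tok.kind == "ssr":
            motif = canonical_motif(tok.motif)
            rec = SSRRecord(seq_id=seq_id, start=start, end=end,
                            motif=motif, period=len(tok.motif),
                            repeats=tok.length / len(tok.motif),
                            length=tok.length)
            ssrs.append(rec)
            if meta.get("zone") in ("inside", "flank"):
                te_ssrs.setdefault(meta["te_id"], []).append(
                    {"zone": meta["zone"], "start": start, "end": end,
                     "motif": motif})
        if tok.kind == "te" or (tok.kind == "ssr"
                                and meta.get("zone") == "inside"):
            te_id = meta["te_id"]
            if te_id not in te_meta:
                te_meta[te_id] = meta
                te_order.append(te_id)
            te_spans.setdefault(te_id, []).append((start, end))
        if "gene_id" in meta and "feature" in meta:
            gid = meta["gene_id"]
            gene_strand[gid] = meta["strand"]
            gene_feats.setdefault(gid, []).append(
                (meta["feature"], start, end, meta["ordinal"]))
    sequences = {seq_id: "".join(pieces)}
    truth = SyntheticTruth(genome_length=pos)
    truth.ssrs = sorted(ssrs, key=lambda r: r.start)
    for te_id in te_order:
        spans = te_spans[te_id]
        meta = te_meta[te_id]
        div = meta["divergence"]
        age = te_age(div, cfg.substitution_rate)
        truth.tes.append(TECopy(
            seq_id=seq_id, start=min(s for s, _ in spans),
            end=max(e for _, e in spans), strand="+",
            family=meta["family"], te_class=meta["te_class"],
            divergence=div, age=age,
            epoch=classify_epoch(age, cfg.split_time)))
        truth.te_carriage.append({
            "te_id": te_id, "family": meta["family"],
            "carried": meta["carried"],
            "ssrs": te_ssrs.get(te_id, [])})
    for gid in sorted(gene_feats, key=lambda g: int(g[1:])):
        feats = gene_feats[gid]
        merged: list[tuple[str, int, int, int]] = []
        for f in sorted(feats, key=lambda f: f[1]):
            if merged and merged[-1][0] == f[0] and merged[-1][3] == f[3] \
                    and merged[-1][2] == f[1]:
                merged[-1] = (f[0], merged[-1][1], f[2], f[3])
            else:
                merged.append(f)
        truth.genes.append(GeneModel(
            gene_id=gid, seq_id=seq_id, strand=gene_strand[gid],
            start=min(f[1] for f in merged), end=max(f[2] for f in merged),
            features=merged))
    return sequences, truth


def expected_ssr_count(cfg: SimConfig, motif: str) -> float:
    """Closed-form expected planted count of one canonical class."""
    cls = canonical_motif(motif)
    total = 0.0
    for spec in cfg.background_ssrs:
        if canonical_motif(spec.motif) == cls:
            total += spec.rate_per_mb * cfg.genome_length / 1e6
    for fam in cfg.te_families:
        w = sum(v for m, v in fam.motif_mix.items()
                if canonical_motif(m) == cls)
        wsum = sum(fam.motif_mix.values())
        total += fam.copy_number * (fam.ssr_carriage + fam.flank_carriage) \
            * (w / wsum if wsum else 0.0)
    g = cfg.genes
    w = sum(v for m, v in g.motif_mix.items() if canonical_motif(m) == cls)
    wsum = sum(g.motif_mix.values())
    total += g.n_genes * (g.intron_ssr_per_gene + g.utr_ssr_per_gene) \
        * (w / wsum if wsum else 0.0)
    return total


def simulate_genome(cfg: SimConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[dict[str, str], SyntheticTruth]:
    """One synthetic genome plus its ground truth (seed-deterministic)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    tokens = build_tokens(cfg, rng)
    return materialize(tokens, cfg)


# -------------------------------------------------------- species pair

def _apply_lineage(tokens: list[_Token], ev: LineageEvents, cfg: SimConfig,
                   rng: np.random.Generator) -> tuple[list[_Token], list[dict]]:
    log: list[dict] = []
    out: list[_Token] = []
    elong_cls = canonical_motif(ev.elongate_motif) if ev.elongate_motif \
        else None
    for tok in tokens:
        tok = copy.deepcopy(tok)
        if tok.kind == "ssr":
            cls = canonical_motif(tok.motif)
            if ev.ssr_deletion_prob and rng.random() < ev.ssr_deletion_prob:
                log.append({"event": "deletion", "motif": cls,
                            "length": tok.length})
                continue
            if elong_cls and cls == elong_cls and ev.elongate_factor != 1.0:
                old = tok.length
                tok.length = int(round(tok.length * ev.elongate_factor))
                log.append({"event": "elongation", "motif": cls,
                            "from": old, "to": tok.length})
        elif ev.substitution_rate > 0:
            tok.seq, _ = _mutate(tok.seq, ev.substitution_rate, rng)
        out.append(tok)
    if ev.extra_motif and ev.extra_rate_per_mb > 0:
        n = rng.poisson(ev.extra_rate_per_mb * cfg.genome_length / 1e6)
        lengths = ev.extra_lengths.sample(n, rng)
        bg_idx = [i for i, t in enumerate(out)
                  if t.kind == "bg" and not t.meta and len(t.seq) > 60]
        for ln in lengths:
            i = bg_idx[int(rng.integers(0, len(bg_idx)))]
            t = out[i]
            cut = int(rng.integers(20, len(t.seq) - 20))
            left = _Token("bg", seq=t.seq[:cut])
            right = _Token("bg", seq=t.seq[cut:])
            new = _ssr_token(ev.extra_motif, int(ln), zone="background")
            out[i:i + 1] = [left, new, right]
            bg_idx = [j for j, t2 in enumerate(out)
                      if t2.kind == "bg" and not t2.meta and len(t2.seq) > 60]
            log.append({"event": "insertion", "motif":
                        canonical_motif(ev.extra_motif), "length": int(ln)})
    if ev.intron_insertion_per_gene > 0:
        intron_idx = [i for i, t in enumerate(out)
                      if t.kind == "bg" and t.meta.get("feature") == "intron"
                      and len(t.seq) > 80]
        by_gene: dict[str, list[int]] = {}
        for i in intron_idx:
            by_gene.setdefault(out[i].meta["gene_id"], []).append(i)
        inserts = []
        for gid, idxs in sorted(by_gene.items()):
            k = rng.poisson(ev.intron_insertion_per_gene)
            for _ in range(k):
                i = idxs[int(rng.integers(0, len(idxs)))]
                inserts.append((i, gid))
        for i, gid in sorted(inserts, reverse=True):
            t = out[i]
            cut = int(rng.integers(30, len(t.seq) - 30))
            motif = _pick_motif(cfg.genes.motif_mix, rng)
            ln = int(cfg.genes.ssr_lengths.sample(1, rng)[0])
            meta = dict(t.meta)
            out[i:i + 1] = [
                _Token("bg", seq=t.seq[:cut], meta=dict(meta)),
                _Token("ssr", motif=motif, length=ln,
                       meta={**meta, "zone": "intron_insertion"}),
                _Token("bg", seq=t.seq[cut:], meta=dict(meta)),
            ]
            log.append({"event": "intron_insertion", "gene": gid,
                        "motif": canonical_motif(motif), "length": ln})
    return out, log


def simulate_species_pair(cfg: SimConfig,
                          events_a: LineageEvents | None = None,
                          events_b: LineageEvents | None = None,
                          rng: np.random.Generator | None = None) -> dict:
    """Two descendant genomes from one ancestor.

    By default lineage A doubles (AT)n lengths and lineage B plants
    extra (AAT)n copies, mirroring the two species-specific expansion
    modes.  Returns a dict with sequences/truth per lineage and the
    one-to-one ortholog pair table.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if events_a is None:
        events_a = LineageEvents(elongate_motif="AT", elongate_factor=2.0)
    if events_b is None:
        events_b = LineageEvents(extra_motif="AAT", extra_rate_per_mb=160.0,
                                 intron_insertion_per_gene=0.2)
    ancestor = build_tokens(cfg, rng)
    tokens_a, log_a = _apply_lineage(ancestor, events_a, cfg, rng)
    tokens_b, log_b = _apply_lineage(ancestor, events_b, cfg, rng)
    cfg_a = copy.deepcopy(cfg)
    cfg_a.seq_id = cfg.seq_id + "_a"
    cfg_b = copy.deepcopy(cfg)
    cfg_b.seq_id = cfg.seq_id + "_b"
    seqs_a, truth_a = materialize(tokens_a, cfg_a)
    seqs_b, truth_b = materialize(tokens_b, cfg_b)
    truth_a.events, truth_b.events = log_a, log_b
    genes = sorted({g.gene_id for g in truth_a.genes}
                   & {g.gene_id for g in truth_b.genes},
                   key=lambda g: int(g[1:]))
    pairs = pd.DataFrame({"gene_id_a": genes, "gene_id_b": genes})
    return {"sequences_a": seqs_a, "truth_a": truth_a,
            "sequences_b": seqs_b, "truth_b": truth_b,
            "ortholog_pairs": pairs}


# ------------------------------------------------------- rearrangements

def _dense_window_centers(ssr_intervals, seq_len: int,
                          window: int = 10_000) -> np.ndarray:
    """Centers of SSR-dense windows (top decile of windowed SSR bp)."""
    n_win = max(1, seq_len // window)
    cov = np.zeros(n_win)
    for s, e in ssr_intervals:
        w0, w1 = s // window, min((e - 1) // window, n_win - 1)
        for w in range(w0, w1 + 1):
            cov[w] += min(e, (w + 1) * window) - max(s, w * window)
    thr = np.quantile(cov, 0.9)
    dense = np.flatnonzero(cov >= max(thr, 1))
    return dense * window + window // 2


def _place_breakpoints(breakpoints: list, spec: RearrangementSpec,
                       seq_len: int, margin: int, max_span: int,
                       ssr_intervals, rng: np.random.Generator) -> None:
    """Junction anchors; with ssr_bias_bp, both anchors land at that
    distance from an SSR-dense window (the blocks the adjacency test
    looks for)."""
    biased = bool(spec.ssr_bias_bp and ssr_intervals)
    centers = _dense_window_centers(ssr_intervals, seq_len) if biased \
        else None

    def anchor() -> int:
        if biased and len(centers):
            lo, hi = spec.ssr_bias_bp
            c = int(centers[int(rng.integers(0, len(centers)))])
            return c + int(rng.integers(lo, hi)) \
                * (1 if rng.random() < 0.5 else -1)
        return int(rng.integers(margin, seq_len - margin))

    for _ in range(spec.n_breakpoints):
        for _try in range(1000):
            a, b = anchor(), anchor()
            if margin <= a < seq_len - margin \
                    and margin <= b < seq_len - margin \
                    and abs(b - a) > max_span + 2 * margin:
                breakpoints.append((int(a), int(b)))
                break
        else:
            raise ValueError("could not place breakpoint inside genome")


def simulate_rearranged_reads(seq_len: int, spec: RearrangementSpec,
                              seq_id: str = "chr1",
                              ssr_intervals: list[tuple[int, int]] | None = None,
                              rng: np.random.Generator | None = None,
                              sample_id: str = "sample",
                              max_span: int = 50_000,
                              breakpoints: list[tuple[int, int]] | None = None
                              ) -> tuple[pd.DataFrame, list[tuple[int, int]]]:
    """Read pairs over a genome with planted rearrangement junctions.

    Junctions join two loci more than *max_span* apart; pairs spanning a
    junction in the derived genome map discordantly in reference space.
    Concordant pairs at ~N(insert_mean, insert_sd) cover the rest; a
    small chimera fraction adds random-mate noise.  When
    ``spec.ssr_bias_bp`` is set, junction anchors are placed at that
    distance range from a planted SSR interval.  Returns (pair table,
    truth junctions [(a, b), ...]).
    """
    if rng is None:
        rng = np.random.default_rng()
    ps = spec.pair_spec
    margin = int(ps.insert_mean * 3)
    if breakpoints is not None:
        breakpoints = list(breakpoints)
    else:
        breakpoints = []
        _place_breakpoints(breakpoints, spec, seq_len, margin, max_span,
                           ssr_intervals, rng)
    n_pairs = int(ps.coverage * seq_len / ps.insert_mean)
    pos1 = rng.integers(0, seq_len - margin, size=n_pairs)
    insert = np.maximum(rng.normal(ps.insert_mean, ps.insert_sd,
                                   size=n_pairs), 2 * ps.read_length + 1)
    pos2 = np.minimum(pos1 + insert.astype(int) - ps.read_length,
                      seq_len - 1)
    frames = [pd.DataFrame({
        "pair_id": [f"c{i}" for i in range(n_pairs)],
        "seq_id_1": seq_id, "pos_1": pos1,
        "seq_id_2": seq_id, "pos_2": pos2,
        "sample_id": sample_id})]
    rate = n_pairs / seq_len
    window = max(int(ps.insert_mean - 2 * ps.read_length), 10)
    k = 0
    for a, b in breakpoints:
        n_disc = rng.poisson(rate * window)
        d = rng.integers(0, window, size=n_disc)
        frames.append(pd.DataFrame({
            "pair_id": [f"d{k}.{i}" for i in range(n_disc)],
            "seq_id_1": seq_id, "pos_1": a - ps.read_length - d,
            "seq_id_2": seq_id,
            "pos_2": b + (window - d) + ps.read_length,
            "sample_id": sample_id}))
        k += 1
    n_chim = rng.poisson(ps.chimera_rate * n_pairs)
    if n_chim:
        frames.append(pd.DataFrame({
            "pair_id": [f"x{i}" for i in range(n_chim)],
            "seq_id_1": seq_id,
            "pos_1": rng.integers(0, seq_len, size=n_chim),
            "seq_id_2": seq_id,
            "pos_2": rng.integers(0, seq_len, size=n_chim),
            "sample_id": sample_id}))
    pairs = pd.concat(frames, ignore_index=True)
    return pairs, breakpoints


# --------------------------------------------------------------- peaks

def simulate_peaks(seq_len: int, ssr_intervals: list[tuple[int, int]],
                   spec: PeakSpec, seq_id: str = "chr1",
                   rng: np.random.Generator | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Accessibility peaks whose SSR-overlap probability follows the
    configured per-stratum curve.

    Returns (all_peaks, diff_peaks with diff_p, truth).  diff peak
    p-values are drawn log-uniformly within their stratum.
    """
    if rng is None:
        rng = np.random.default_rng()
    ssr_arr = np.array(sorted(ssr_intervals)) if ssr_intervals else \
        np.empty((0, 2), int)

    def draw_peak(overlap: bool, width: int) -> tuple[int, int]:
        if overlap and len(ssr_arr):
            s, e = ssr_arr[int(rng.integers(0, len(ssr_arr)))]
            c = int(rng.integers(s, max(e, s + 1)))
            start = max(0, c - width // 2)
            return start, min(start + width, seq_len)
        for _ in range(200):
            start = int(rng.integers(0, seq_len - width))
            end = start + width
            if not len(ssr_arr):
                return start, end
            i = np.searchsorted(ssr_arr[:, 1], start, side="right")
            if i >= len(ssr_arr) or ssr_arr[i, 0] >= end:
                return start, end
        return start, end  # dense genomes: accept residual overlap

    thresholds = sorted(spec.thresholds, reverse=True)  # loosest first

    def stratum_of(p: float) -> int:
        s = -1
        for i, t in enumerate(thresholds):
            if p < t:
                s = i
        return s

    rows_all, rows_diff, rows_truth = [], [], []
    widths = np.clip(rng.normal(spec.width_mean, spec.width_sd,
                                size=spec.n_all + spec.n_diff),
                     150, 1500).astype(int)
    # normal (non-differential) peaks
    for i in range(spec.n_all):
        ov = bool(rng.random() < spec.base_overlap_prob)
        s, e = draw_peak(ov, int(widths[i]))
        pid = f"peak{i}"
        rows_all.append((seq_id, s, e, pid, 0, ".", 0.0, 0.0, 0.0, -1))
        rows_truth.append((pid, False, -1, np.nan, ov))
    # differential peaks: stratum chosen uniformly, p log-uniform inside
    edges = [math.log10(t) for t in thresholds] + \
        [math.log10(thresholds[-1]) - 5]
    for j in range(spec.n_diff):
        stratum = int(rng.integers(0, len(thresholds)))
        lo, hi = edges[stratum + 1], edges[stratum]
        logp = rng.uniform(lo, hi)
        p = 10 ** logp
        # membership is nested: overlap prob follows the strictest
        # stratum the peak belongs to
        prob = spec.stratum_overlap_probs[stratum_of(p)]
        ov = bool(rng.random() < prob)
        s, e = draw_peak(ov, int(widths[spec.n_all + j]))
        pid = f"diff{j}"
        rows_diff.append((seq_id, s, e, pid, 0, ".", 0.0, -logp, 0.0, -1, p))
        rows_truth.append((pid, True, stratum, p, ov))
    all_peaks = pd.DataFrame(rows_all, columns=[
        "seq_id", "start", "end", "peak_id", "score", "strand", "signal",
        "pvalue", "qvalue", "summit"])
    diff_peaks = pd.DataFrame(rows_diff, columns=[
        "seq_id", "start", "end", "peak_id", "score", "strand", "signal",
        "pvalue", "qvalue", "summit", "diff_p"])
    truth = pd.DataFrame(rows_truth, columns=[
        "peak_id", "differential", "stratum", "diff_p", "ssr_overlap"])
    return all_peaks, diff_peaks, truth
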