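"""SSR (microsatellite) detection.

Finds maximal tandem repeats of 1-6 bp motifs in DNA sequence.  Two
modes are supported:

* ``perfect`` — pure repeat stretches only; a record is a maximal run
  of positions satisfying ``seq[i] == seq[i - period]``.
* ``imperfect`` — perfect runs of the same period and motif class that
  are separated by at most ``max_interruption`` bp are chained into one
  record, in the spirit of mismatched-mode microsatellite miners; gap
  bases are counted as mismatches and reported as a purity.  A chained
  record must contain at least one pure run of ``seed_min_length`` bp.

Candidate records at different periods whose leading motif is reducible
(e.g. an ``ATAT`` unit, already covered at period 2) are dropped, and
overlapping candidates of different motif classes are resolved
deterministically: longest wins, ties broken by lower period, then by
leftmost start.  Assembly-gap characters (``N``) never match, so records
cannot span gaps.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .motifs import canonical_motif, is_primitive

#: per-period default minimum total length in bp (index 1..6)
DEFAULT_MIN_LENGTH = {1: 12, 2: 12, 3: 12, 4: 16, 5: 20, 6: 24}


@dataclass(frozen=True)
class SSRRecord:
    """One detected tandem repeat (0-based, half-open coordinates)."""

    seq_id: str
    start: int
    end: int
    motif: str          # canonical class representative
    period: int
    repeats: float      # length / period (real-valued)
    length: int
    mismatches: int = 0
    purity: float = 1.0


@dataclass
class DetectionConfig:
    """Parameters of the SSR search.

    min_length maps period (1-6) to the minimum total record length in
    bp; mode is ``perfect`` or ``imperfect``.  In imperfect mode a seed
    must be a pure run of at least ``seed_min_length`` bp before it is
    extended across interruptions of at most ``max_interruption`` bp.
    ``merge_distance`` > 0 additionally reports compound repeats (see
    :func:`merge_compound`).
    """

    min_length: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_LENGTH))
    mode: str = "perfect"
    seed_min_length: int = 8
    max_interruption: int = 3
    min_purity: float = 0.5
    merge_distance: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("perfect", "imperfect"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for p in range(1, 7):
            if p not in self.min_length:
                raise ValueError(f"min_length missing period {p}")
            if self.min_length[p] < 2 * p:
                raise ValueError(
                    f"min_length[{p}]={self.min_length[p]} < 2*period")


def _true_runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start/end indices of maximal runs of True in a boolean array."""
    if mask.size == 0:
        return np.empty(0, int), np.empty(0, int)
    edges = np.flatnonzero(np.diff(np.concatenate(
        ([False], mask, [False])).astype(np.int8)))
    return edges[0::2], edges[1::2]


def _period_runs(arr: np.ndarray, valid: np.ndarray, period: int):
    """Maximal perfect runs at *period*: pairs (start, end) of intervals
    [start, end) with end-start > period and seq[i]==seq[i-period]
    throughout (N never matches)."""
    if arr.size <= period:
        return np.empty(0, int), np.empty(0, int)
    # a position enters a run only if the whole period+1 window is N-free
    c = np.concatenate(([0], np.cumsum(~valid)))
    clean = (c[period + 1:] - c[:-(period + 1)]) == 0
    m = (arr[period:] == arr[:-period]) & clean
    s, e = _true_runs(m)
    return s, e + period  # interval end includes the trailing period bases


def _chain_runs(seq: str, starts, ends, period: int,
                config: "DetectionConfig") -> list[tuple[int, int, int]]:
    """Chain perfect runs at one period across short interruptions.

    Consecutive runs of the same canonical class with a gap of at most
    ``max_interruption`` bp (no N in the gap) merge into one candidate;
    gap bases count as mismatches.  Returns (start, end, mismatches)
    candidates passing the length/purity/seed filters.
    """
    min_len = config.min_length[period]
    seed = max(config.seed_min_length, 2 * period)
    out: list[tuple[int, int, int]] = []
    cur = None  # [start, end, mism, max_run, cls]

    def flush() -> None:
        if cur is None:
            return
        start, end, mism, max_run = cur[0], cur[1], cur[2], cur[3]
        length = end - start
        if length < min_len:
            return
        if mism > 0:
            purity = 1.0 - mism / length
            if purity <= config.min_purity or max_run < seed:
                return
        out.append((start, end, mism))

    for s, e in zip(starts, ends):
        s, e = int(s), int(e)
        motif = seq[s:s + period]
        if not is_primitive(motif):
            continue
        cls = canonical_motif(motif)
        gap = None if cur is None else s - cur[1]
        if cur is not None and 0 < gap <= config.max_interruption \
                and cls == cur[4] and "N" not in seq[cur[1]:s]:
            cur[1] = e
            cur[2] += gap
            cur[3] = max(cur[3], e - s)
        else:
            flush()
            cur = [s, e, 0, e - s, cls]
    flush()
    return out


def _resolve_overlaps(cands: list[tuple]) -> list[tuple]:
    """Greedy selection: longest first, tie -> lower period -> leftmost.

    cands items are (seq_id, start, end, period, motif, mismatches).
    Accepted records never overlap (records at the same period are
    disjoint by construction; cross-period overlaps are resolved here).
    """
    order = sorted(cands, key=lambda c: (-(c[2] - c[1]), c[3], c[0], c[1]))
    kept: list[tuple] = []
    occupied: dict[str, tuple[list[int], list[int]]] = {}
    for c in order:
        seq_id, start, end = c[0], c[1], c[2]
        starts, ends = occupied.setdefault(seq_id, ([], []))
        i = bisect.bisect_right(starts, start)
        clash = (i < len(starts) and starts[i] < end) or \
                (i > 0 and ends[i - 1] > start)
        if clash:
            continue
        starts.insert(i, start)
        ends.insert(i, end)
        kept.append(c)
    return kept


def find_ssrs(seq: str, config: DetectionConfig | None = None,
              seq_id: str = "seq") -> list[SSRRecord]:
    """Detect SSRs in one sequence.

    Returns maximal, mutually non-overlapping records sorted by
    (seq_id, start).  Empty input yields an empty list.
    """
    if config is None:
        config = DetectionConfig()
    seq = seq.upper()
    if not seq:
        return []
    if not set(seq) <= set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"non-ACGTN characters in sequence: {bad}")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = arr != ord("N")

    cands: list[tuple] = []
    for period in range(1, 7):
        min_len = config.min_length[period]
        starts, ends = _period_runs(arr, valid, period)
        if config.mode == "perfect":
            keep = (ends - starts) >= min_len
            for s, e in zip(starts[keep], ends[keep]):
                motif = seq[s:s + period]
                if not is_primitive(motif):
                    continue
                cands.append((seq_id, int(s), int(e), period, motif, 0))
        else:
            for s, e, mism in _chain_runs(seq, starts, ends, period, config):
                cands.append((seq_id, s, e, period, seq[s:s + period], mism))

    records = []
    for seq_id_, s, e, period, motif, mism in _resolve_overlaps(cands):
        length = e - s
        records.append(SSRRecord(
            seq_id=seq_id_, start=s, end=e,
            motif=canonical_motif(motif), period=period,
            repeats=length / period, length=length,
            mismatches=mism, purity=1.0 - mism / length))
    records.sort(key=lambda r: (r.seq_id, r.start))
    return records


def find_ssrs_genome(sequences: dict[str, str],
                     config: DetectionConfig | None = None
                     ) -> list[SSRRecord]:
    """Run :func:`find_ssrs` over a dict of sequences."""
    out: list[SSRRecord] = []
    for seq_id in sequences:
        out.extend(find_ssrs(sequences[seq_id], config, seq_id=seq_id))
    return out


def merge_compound(records: list[SSRRecord], max_gap: int) -> list[SSRRecord]:
    """Merge neighbouring SSRs closer than *max_gap* bp into compound
    records (motif classes joined by '/'), the alternative counting for
    compound repeats.  Input records must be non-overlapping."""
    out: list[SSRRecord] = []
    for rec in sorted(records, key=lambda r: (r.seq_id, r.start)):
        if out and rec.seq_id == out[-1].seq_id \
                and rec.start - out[-1].end <= max_gap:
            prev = out.pop()
            length = rec.end - prev.start
            motifs = sorted(set(prev.motif.split("/")) | {rec.motif})
            mism = prev.mismatches + rec.mismatches + (rec.start - prev.end)
            out.append(SSRRecord(
                seq_id=rec.seq_id, start=prev.start, end=rec.end,
                motif="/".join(motifs), period=min(prev.period, rec.period),
                repeats=length / min(prev.period, rec.period), length=length,
                mismatches=mism, purity=1.0 - mism / length))
        else:
            out.append(rec)
    return out
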