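"""Independent brute-force oracles used to check the fast implementations.

These deliberately re-derive results by direct enumeration (cubic-time
tandem-repeat search, all-pairs interval arithmetic) and share no code
with the library routines they verify, beyond the documented tie-break
policy for overlapping candidates.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_canonical(motif: str) -> str:
    """Minimum over all rotations of the motif and its reverse
    complement, enumerated explicitly."""
    rc = "".join(_COMP[c] for c in reversed(motif))
    cands = []
    for m in (motif, rc):
        for i in range(len(m)):
            cands.append(m[i:] + m[:i])
    return min(cands)


def _primitive(motif: str) -> bool:
    for q in range(1, len(motif)):
        if len(motif) % q == 0 and motif == motif[:q] * (len(motif) // q):
            return False
    return True


def brute_force_ssrs(seq: str, min_length=None) -> set[tuple]:
    """Enumerate every maximal perfect tandem repeat by direct extension
    from every (start, period) and apply the same thresholds and
    overlap-resolution policy as the detector's contract.

    Returns a set of (start, end, period, canonical_motif).
    """
    if min_length is None:
        min_length = {1: 12, 2: 12, 3: 12, 4: 16, 5: 20, 6: 24}
    seq = seq.upper()
    n = len(seq)
    candidates = set()
    for period in range(1, 7):
        for s in range(n - period + 1):
            motif = seq[s:s + period]
            if "N" in motif or not _primitive(motif):
                continue
            # left-maximality: extending one base left must fail
            if s > 0 and seq[s - 1] != "N" and seq[s - 1] == seq[s - 1 + period]:
                continue
            e = s + period
            while e < n and seq[e] != "N" and seq[e] == seq[e - period]:
                e += 1
            if e - s >= min_length[period]:
                candidates.add((s, e, period, oracle_canonical(motif)))
    # longest first, tie -> lower period -> leftmost; quadratic overlap scan
    kept: list[tuple] = []
    for c in sorted(candidates, key=lambda c: (-(c[1] - c[0]), c[2], c[0])):
        if all(c[1] <= k[0] or c[0] >= k[1] for k in kept):
            kept.append(c)
    return set(kept)


def brute_force_assign(ssrs, tes, flank_bp: int = 100) -> list[tuple]:
    """All-pairs SSR->TE zone resolver mirroring the assignment
    contract: inside beats flank, largest overlap wins, ties to nearest
    TE start then leftmost TE.  Returns (zone, te_index|None) per SSR."""
    out = []
    for ssr in ssrs:
        best = None  # (zone_rank, -overlap, dist, te_start, idx, zone)
        for idx, te in enumerate(tes):
            if te.seq_id != ssr.seq_id:
                continue
            mid = (ssr.start + ssr.end) / 2
            cands = [("inside", 0, te.start, te.end)]
            left = (max(0, te.start - flank_bp), te.start)
            right = (te.end, te.end + flank_bp)
            if te.strand == "-":
                up, down = right, left
            else:
                up, down = left, right
            cands.append(("upstream_flank", 1, up[0], up[1]))
            cands.append(("downstream_flank", 1, down[0], down[1]))
            for zone, rank, zs, ze in cands:
                ov = min(ssr.end, ze) - max(ssr.start, zs)
                if ov >= 1:
                    key = (rank, -ov, abs(mid - te.start), te.start, idx)
                    if best is None or key < best[0]:
                        best = (key, zone, idx)
    # inside beats flank even across TEs: filter done via rank in key
        if best is None:
            out.append(("outside", None))
        else:
            out.append((best[1], best[2]))
    return out


def brute_force_content(peaks, features) -> float:
    """Per-base set arithmetic for feature content in peaks."""
    covered = 0
    total = 0
    feat_bases: dict[str, set[int]] = {}
    for f in features.itertuples():
        feat_bases.setdefault(f.seq_id, set()).update(
            range(int(f.start), int(f.end)))
    for p in peaks.itertuples():
        total += int(p.end) - int(p.start)
        bases = feat_bases.get(p.seq_id, set())
        covered += sum(1 for x in range(int(p.start), int(p.end))
                       if x in bases)
    return covered / total
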