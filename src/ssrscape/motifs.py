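"""Motif canonicalization for SSR classes.

An SSR class is named by one representative motif so that, e.g., (TA)n,
(AT)n on the plus strand and (AT)n on the minus strand all belong to the
single class (AT)n.  The representative is the lexicographically smallest
string among all rotations of the motif and all rotations of its reverse
complement.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT(N) string."""
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def is_primitive(motif: str) -> bool:
    """True if *motif* is not itself a tandem repeat of a shorter motif.

    Uses the classical doubling trick: ``motif`` has a smaller period
    iff it occurs in ``(motif + motif)[1:-1]``.
    """
    return (motif + motif).find(motif, 1) == len(motif)


def canonical_motif(motif: str) -> str:
    """Canonical class representative of an SSR motif.

    Minimum over all rotations of the motif and of its reverse
    complement; idempotent by construction.

    Raises
    ------
    ValueError
        If the motif is empty, longer than 6 bp, contains non-ACGT
        characters, or is reducible (itself a tandem repeat of a
        shorter motif, e.g. ``"ATAT"``).
    """
    if not 1 <= len(motif) <= 6:
        raise ValueError(f"motif length must be 1-6, got {motif!r}")
    motif = motif.upper()
    if not set(motif) <= _ALPHABET:
        raise ValueError(f"non-ACGT character in motif {motif!r}")
    if not is_primitive(motif):
        raise ValueError(f"reducible motif {motif!r}")
    rc = motif.translate(_COMPLEMENT)[::-1]
    candidates = [motif[i:] + motif[:i] for i in range(len(motif))]
    candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)
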