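"""Small nucleotide utilities: IUPAC code semantics, reverse complement, motif scan."""

from __future__ import annotations

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_compatible(observed: str, pattern_char: str) -> bool:
    """True when the observed code could denote a base the pattern char allows.

    A gap never matches.  An ambiguity code in the observed sequence matches
    when its base set intersects the pattern's: the motif *could* be present,
    which is the conservative reading for a diagnostic cross-reactivity screen.
    """
    obs = IUPAC_SETS.get(observed)
    pat = IUPAC_SETS.get(pattern_char)
    if obs is None or pat is None:
        return False
    return bool(obs & pat)


def matches_iupac(seq: str, pattern: str) -> bool:
    """Full-length IUPAC pattern match (len(seq) must equal len(pattern))."""
    if len(seq) != len(pattern):
        return False
    return all(iupac_compatible(s, p) for s, p in zip(seq, pattern))


def contains_motif(seq: str, pattern: str) -> bool:
    """Does any window of seq match the IUPAC pattern (forward strand only)?"""
    k = len(pattern)
    return any(matches_iupac(seq[i:i + k], pattern) for i in range(len(seq) - k + 1))


def max_homopolymer(seq: str) -> int:
    """Length of the longest single-base run."""
    best = run = 0
    prev = ""
    for ch in seq:
        run = run + 1 if ch == prev else 1
        prev = ch
        best = max(best, run)
    return best
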