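"""Small shared sequence helpers."""

from __future__ import annotations

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: The 12 ordered unequal base pairs (mutation types), lexicographic.
MUTATION_TYPES: tuple[tuple[str, str], ...] = tuple(
    (r, a) for r in BASES for a in BASES if r != a
)


def revcomp(seq: str) -> str:
    """Reverse complement of ``seq`` (A<->T, C<->G, N fixed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G/C bases in ``seq``."""
    return (seq.count("G") + seq.count("C")) / len(seq)


def is_acgt(seq: str) -> bool:
    return bool(seq) and all(c in BASES for c in seq)
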