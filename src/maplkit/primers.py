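"""Degenerate-primer logic for the COI mini-barcode.

The 133 bp mini-barcode is amplified with a degenerate primer pair
(forward MG-LCO1490, reverse MG-R).  Because the primers carry IUPAC
degeneracies, "does the primer bind this template" is a set-membership
question per position, and a mismatch close to the primer 3' end is
far more damaging to amplification than one near the 5' end: the
polymerase extends from the 3' end, so a 3'-proximal mismatch
essentially aborts amplification of that template.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "FORWARD_PRIMER",
    "REVERSE_PRIMER",
    "INSERT_LENGTH",
    "IUPAC_SETS",
    "PrimerPair",
    "complement",
    "reverse_complement",
    "count_primer_mismatches",
    "expand_degenerate",
    "binding_efficiency",
]

#: Universal COI mini-barcode primers (5'->3').
FORWARD_PRIMER = "ATTCHACDAAYCAYAARGAYATYGG"        # MG-LCO1490
REVERSE_PRIMER = "ACTATAAAARAAAYTATDAYAAADGCRTG"    # MG-R

#: Length of the enclosed mini-barcode insert.
INSERT_LENGTH = 133

#: Positions (counted from the primer 3' end, 1-based) whose mismatches
#: are treated as amplification-critical.
CRITICAL_3PRIME_WINDOW = 10

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"),
    "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N",
}

#: Equality pairs so edlib treats IUPAC codes as matching their base sets.
IUPAC_EQUALITIES = [
    (code, base)
    for code, bases in IUPAC_SETS.items()
    if len(bases) > 1
    for base in bases
]


def complement(base: str) -> str:
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise ValueError(f"non-IUPAC character {base!r}") from None


def reverse_complement(seq: str) -> str:
    return "".join(complement(b) for b in reversed(seq))


def _validate(seq: str, what: str) -> None:
    bad = set(seq) - set(IUPAC_SETS)
    if bad:
        raise ValueError(f"non-IUPAC character(s) {sorted(bad)} in {what}")


def count_primer_mismatches(
    template: str, primer: str, orientation: str = "forward"
) -> list[tuple[int, str, str]]:
    """Positions where a template does not satisfy a degenerate primer.

    ``template`` is the primer-binding segment of the merged read
    (5'->3', read orientation) and must have the primer's length.  For
    ``orientation="forward"`` the segment is compared code-by-code
    against the primer; for ``"reverse"`` it is compared against the
    primer's reverse complement (the reverse primer appears
    reverse-complemented at the 3' end of a merged read).

    Returns ``[(position_from_3prime, template_base, primer_code), ...]``
    with 1-based positions counted from the primer's 3' end; an empty
    list means perfect binding.
    """
    template = template.upper()
    primer = primer.upper()
    _validate(template, "template")
    _validate(primer, "primer")
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if len(template) != len(primer):
        raise ValueError(
            f"template length {len(template)} != primer length {len(primer)}"
        )
    n = len(primer)
    mismatches: list[tuple[int, str, str]] = []
    if orientation == "forward":
        for i, (t, p) in enumerate(zip(template, primer)):
            if t not in IUPAC_SETS[p]:
                mismatches.append((n - i, t, p))
    else:
        rc = reverse_complement(primer)
        # rc[0] corresponds to the primer's 3'-terminal base.
        for i, (t, p) in enumerate(zip(template, rc)):
            if t not in IUPAC_SETS[p]:
                mismatches.append((i + 1, t, primer[n - 1 - i]))
    return sorted(mismatches)


def expand_degenerate(primer: str, rng) -> str:
    """One concrete realisation of a degenerate primer (random choice
    among the allowed bases at each degenerate position)."""
    _validate(primer, "primer")
    return "".join(
        b if len(IUPAC_SETS[b]) == 1 else rng.choice(sorted(IUPAC_SETS[b]))
        for b in primer
    )


def binding_efficiency(
    mismatches: list[tuple[int, str, str]],
    critical_window: int = CRITICAL_3PRIME_WINDOW,
    per_mismatch_penalty: float = 0.9,
) -> float:
    """Relative amplification efficiency implied by a mismatch list.

    Any mismatch within ``critical_window`` bases of the primer 3' end
    aborts extension (efficiency 0); each remaining (5'-side) mismatch
    applies a mild multiplicative penalty.
    """
    if any(pos <= critical_window for pos, _, _ in mismatches):
        return 0.0
    return per_mismatch_penalty ** len(mismatches)


@dataclass(frozen=True)
class PrimerPair:
    """A degenerate primer pair with a trimming mismatch tolerance."""

    forward: str = FORWARD_PRIMER
    reverse: str = REVERSE_PRIMER
    max_mismatch: int = 2

    def __post_init__(self) -> None:
        _validate(self.forward, "forward primer")
        _validate(self.reverse, "reverse primer")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
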