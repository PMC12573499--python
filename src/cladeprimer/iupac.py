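"""IUPAC nucleotide code tables and set semantics.

All mismatch logic in the toolkit is defined on IUPAC base *sets*: two codes
match iff their sets intersect (so M = {A,C} matches A but not G). The gap
character '-' carries an empty set and therefore mismatches everything,
including itself.
"""

from __future__ import annotations

from .errors import IllegalCharacterError

# code -> frozenset of concrete bases
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: reverse lookup: frozenset of bases -> minimal covering code
SET_TO_CODE: dict[frozenset[str], str] = {s: c for c, s in IUPAC_SETS.items()}

COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "-": "-",
}

GAP = "-"
CONCRETE = "ACGT"
ALPHABET = frozenset(IUPAC_SETS) | {GAP}


def base_set(code: str) -> frozenset[str]:
    """Return the concrete-base set for one IUPAC code ('-' -> empty set)."""
    if code == GAP:
        return frozenset()
    try:
        return IUPAC_SETS[code]
    except KeyError:
        raise IllegalCharacterError(f"not an IUPAC nucleotide code: {code!r}") from None


def codes_match(a: str, b: str) -> bool:
    """True iff the base sets of two codes intersect (gap never matches)."""
    return bool(base_set(a) & base_set(b))


def minimal_code(bases: set[str] | frozenset[str]) -> str:
    """Smallest IUPAC code covering a non-empty set of concrete bases."""
    key = frozenset(bases)
    if not key:
        raise ValueError("cannot encode an empty base set")
    if not key <= IUPAC_SETS["N"]:
        raise IllegalCharacterError(f"non-ACGT bases in set: {sorted(key)}")
    return SET_TO_CODE[key]


def degeneracy(sequence: str) -> int:
    """Product of per-position base-set cardinalities."""
    d = 1
    for c in sequence:
        d *= len(base_set(c))
    return d


def reverse_complement(sequence: str) -> str:
    """Reverse complement honoring ambiguity codes (M<->K, R<->Y, ...)."""
    try:
        return "".join(COMPLEMENT[c] for c in reversed(sequence))
    except KeyError as exc:
        raise IllegalCharacterError(f"cannot complement {exc.args[0]!r}") from None


def validate_sequence(sequence: str, *, allow_gaps: bool = False) -> None:
    """Raise IllegalCharacterError on any character outside the alphabet."""
    allowed = ALPHABET if allow_gaps else frozenset(IUPAC_SETS)
    bad = set(sequence) - allowed
    if bad:
        raise IllegalCharacterError(
            f"illegal sequence character(s): {sorted(bad)}"
        )
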