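"""Primers with IUPAC degeneracy, LNA annotations, and adaptor prefixes.

A primer is written in a vendor-style markup where ``+`` flags the following
base as a locked nucleic acid (LNA) residue, e.g.::

    GTTAAAAAGCTCGTAGTTGAA+TTT      (forward, LNA at core position 22)
    CAACT+ATCCCTATTMATCATTAC       (reverse, LNA at 6, mixed base M at 15)

LNA residues carry a bicyclic sugar that raises the duplex melting
temperature and sharpens discrimination against a mismatched template; here
they are modeled structurally (positions) plus a configurable per-residue Tm
increment. Sequencing adaptors are modeled as plain length-bearing ACGT
prefixes: they contribute to the adaptor-linked amplicon length and nothing
else.

Positions are 1-based from the 5' end of the core; "position from the 3'
end" is length - pos5 + 1. Reports print both conventions with labels.
"""

from __future__ import annotations

import csv
import importlib.resources
import itertools
import statistics
from dataclasses import dataclass, field
from pathlib import Path

from Bio.SeqUtils import MeltingTemp

from . import iupac
from .errors import DegeneracyCapError, IncomparablePrimersError, PrimerSpecError

__all__ = [
    "Primer",
    "PrimerComparison",
    "TmEstimate",
    "TmConfig",
    "parse_primer_spec",
    "expand_degenerate",
    "reverse_complement",
    "estimate_tm",
    "compare_primer_to_reference",
    "load_primer_table",
    "builtin_primers",
]

reverse_complement = iupac.reverse_complement


@dataclass(frozen=True)
class Primer:
    name: str
    core: str
    lna_positions: frozenset[int] = frozenset()
    adaptor: str = ""
    orientation: str = "forward"

    def __post_init__(self) -> None:
        iupac.validate_sequence(self.core)
        if not self.core:
            raise PrimerSpecError("empty primer core")
        if self.orientation not in ("forward", "reverse"):
            raise PrimerSpecError(f"bad orientation {self.orientation!r}")
        bad = [p for p in self.lna_positions if not 1 <= p <= len(self.core)]
        if bad:
            raise PrimerSpecError(f"LNA positions out of range: {bad}")
        if self.adaptor and set(self.adaptor) - set("ACGT"):
            raise PrimerSpecError("adaptor must be plain ACGT")

    def __len__(self) -> int:
        return len(self.core)

    @property
    def degeneracy(self) -> int:
        return iupac.degeneracy(self.core)

    def pos_from_3prime(self, pos5: int) -> int:
        """Convert a 1-based 5'-position to its 1-based 3'-end counterpart."""
        return len(self.core) - pos5 + 1

    @property
    def lna_positions_from_3prime(self) -> frozenset[int]:
        return frozenset(self.pos_from_3prime(p) for p in self.lna_positions)

    def spec_markup(self) -> str:
        """Render the core back into the '+' markup dialect."""
        out = []
        for i, base in enumerate(self.core, start=1):
            if i in self.lna_positions:
                out.append("+")
            out.append(base)
        return "".join(out)


@dataclass(frozen=True)
class PrimerComparison:
    """Structural offsets of a primer against a reference primer.

    Extensions are signed base counts relative to the reference's termini
    (positive = the primer extends past the reference; negative =
    truncation). Substitutions count only aligned positions whose IUPAC
    base-sets are disjoint, so a degenerate M aligned to an A is compatible,
    not a substitution.
    """

    five_prime_extension: int
    three_prime_extension: int
    internal_substitutions: int
    aligned_overlap: int


@dataclass(frozen=True)
class TmEstimate:
    tm_min: float
    tm_mean: float
    tm_max: float
    lna_bonus: float

    def __post_init__(self) -> None:
        assert self.tm_min <= self.tm_mean <= self.tm_max


@dataclass(frozen=True)
class TmConfig:
    """Nearest-neighbor Tm settings (unified DNA parameters).

    The LNA contribution is an additive per-residue increment; a full LNA
    nearest-neighbor parameter set is out of scope.
    """

    na_mM: float = 50.0
    oligo_nM: float = 250.0
    lna_increment_c: float = 4.0
    degeneracy_cap: int = 64


def parse_primer_spec(
    text: str,
    name: str = "primer",
    orientation: str = "forward",
    adaptor: str = "",
) -> Primer:
    """Parse '+'-markup primer text into a Primer.

    An optional leading ``adaptor:SEQ`` field (whitespace-separated) sets the
    adaptor; an explicit `adaptor` argument overrides it.
    """
    text = text.strip()
    if text.lower().startswith("adaptor:"):
        head, _, rest = text.partition(" ")
        parsed_adaptor = head[len("adaptor:"):]
        if not rest.strip():
            raise PrimerSpecError("adaptor field without a primer core")
        text = rest.strip()
        adaptor = adaptor or parsed_adaptor
    core_chars: list[str] = []
    lna: set[int] = set()
    pending_lna = False
    for ch in text:
        if ch == "+":
            if pending_lna:
                raise PrimerSpecError("'++' in primer spec")
            pending_lna = True
            continue
        if ch.upper() not in iupac.IUPAC_SETS:
            raise PrimerSpecError(f"non-IUPAC character {ch!r} in primer spec")
        core_chars.append(ch.upper())
        if pending_lna:
            lna.add(len(core_chars))
            pending_lna = False
    if pending_lna:
        raise PrimerSpecError("'+' at end of spec not followed by a base")
    if not core_chars:
        raise PrimerSpecError("empty primer spec")
    return Primer(
        name=name,
        core="".join(core_chars),
        lna_positions=frozenset(lna),
        adaptor=adaptor,
        orientation=orientation,
    )


def expand_degenerate(primer: Primer | str) -> list[str]:
    """All concrete sequences matching the degenerate core, lexicographic."""
    core = primer.core if isinstance(primer, Primer) else primer
    choices = [sorted(iupac.base_set(c)) for c in core]
    return ["".join(p) for p in itertools.product(*choices)]


def estimate_tm(primer: Primer, config: TmConfig | None = None) -> TmEstimate:
    """Nearest-neighbor Tm summarized over degenerate expansions.

    Each expansion's Tm gets the LNA bonus (increment x number of LNA
    residues) added before the min/mean/max summary.
    """
    config = config or TmConfig()
    if primer.degeneracy > config.degeneracy_cap:
        raise DegeneracyCapError(
            f"degeneracy {primer.degeneracy} exceeds cap {config.degeneracy_cap}"
        )
    bonus = config.lna_increment_c * len(primer.lna_positions)
    tms = [
        MeltingTemp.Tm_NN(seq, Na=config.na_mM, dnac1=config.oligo_nM, dnac2=0)
        + bonus
        for seq in expand_degenerate(primer)
    ]
    return TmEstimate(
        tm_min=min(tms), tm_mean=statistics.fmean(tms), tm_max=max(tms),
        lna_bonus=bonus,
    )


def compare_primer_to_reference(
    primer: Primer, reference: Primer, min_overlap_matches: int = 8
) -> PrimerComparison:
    """Anchor the primer on a reference by exhaustive ungapped offset scan.

    Both cores are <= ~40 nt so brute force over every offset is exact. The
    chosen offset maximizes IUPAC-compatible aligned positions (tie-break:
    fewest substitutions, then longest overlap, then smallest offset).
    """
    p, r = primer.core, reference.core
    best = None
    for offset in range(-(len(p) - 1), len(r)):
        # primer position i aligns reference position i + offset
        lo = max(0, -offset)
        hi = min(len(p), len(r) - offset)
        overlap = hi - lo
        if overlap <= 0:
            continue
        matches = sum(
            iupac.codes_match(p[i], r[i + offset]) for i in range(lo, hi)
        )
        subs = overlap - matches
        key = (matches, -subs, overlap, -abs(offset))
        if best is None or key > best[0]:
            best = (key, offset, overlap, subs)
    assert best is not None
    key, offset, overlap, subs = best
    if key[0] < min_overlap_matches:
        raise IncomparablePrimersError(
            f"best anchored overlap has only {key[0]} compatible bases "
            f"(need >= {min_overlap_matches})"
        )
    return PrimerComparison(
        five_prime_extension=-offset,
        three_prime_extension=(len(p) + offset) - len(r),
        internal_substitutions=subs,
        aligned_overlap=overlap,
    )


def load_primer_table(path: str | Path) -> dict[str, Primer]:
    """Read a primer definition TSV (columns: name/spec/orientation/adaptor)."""
    primers: dict[str, Primer] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            primer = parse_primer_spec(
                row["spec"],
                name=row["name"],
                orientation=row["orientation"],
                adaptor=(row.get("adaptor") or "").strip(),
            )
            primers[primer.name] = primer
    return primers


_BUILTIN: dict[str, Primer] | None = None


def builtin_primers() -> dict[str, Primer]:
    """The shipped primer definitions (clade-specific set, published
    references AM-Sal-F/AMDGR, and the universal control sets)."""
    global _BUILTIN
    if _BUILTIN is None:
        ref = importlib.resources.files("cladeprimer").joinpath("data/primers.tsv")
        with importlib.resources.as_file(ref) as path:
            _BUILTIN = load_primer_table(path)
    return dict(_BUILTIN)
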