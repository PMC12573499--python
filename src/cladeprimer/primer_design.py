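"""Clade-discriminative primer design over a labeled multiple alignment.

The procedure formalizes what a primer designer does by eye on a stacked
alignment: find window pairs whose consensus over the *target* rows is
nearly invariant (low IUPAC degeneracy, full coverage) while every
*excluded* group carries mismatches against that consensus — preferentially
near the 3' end, where mismatches actually stop the polymerase. Candidate
pairs are ranked lexicographically by (worst-case exclusion margin, target
coverage, 3'-weighted discrimination); this ranking is the module's own
formalization — the window search it automates was historically manual.

LNA placement follows the published design logic: a locked base is proposed
exactly where *every* plant row mismatches the consensus, choosing the
positions with the highest 3'-proximity weight (at most `max_lna` per
primer).

Two scoring paths exist on purpose: `score_candidate_window` evaluates one
window directly from the alignment (the reference semantics), while
`design_primer_pairs` uses an O(1)-per-window prefix-sum scan precomputed
per column; the test suite asserts they agree.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import iupac
from .errors import CladePrimerError
from .primer_model import Primer
from .seq_io import Alignment, TaxonMap

__all__ = [
    "DesignConstraints",
    "WindowScore",
    "DesignCandidate",
    "ConsensusError",
    "column_consensus",
    "score_candidate_window",
    "design_primer_pairs",
    "suggest_modifications",
]

#: phyla treated as plants for LNA placement
PLANT_PHYLA = frozenset({"Tracheophyta", "Streptophyta", "Viridiplantae"})


@dataclass(frozen=True)
class DesignConstraints:
    min_primer_len: int = 18
    max_primer_len: int = 26
    min_product_bp: int = 200
    max_product_bp: int = 350
    degeneracy_cap: int = 4
    min_target_coverage: float = 0.9
    coverage_max_mismatches: int = 1
    #: 3'-proximity weights: positions 1-4 from the 3' end score 3, 5-8
    #: score 2, the rest score 1 (3'-proximal mismatches discriminate hardest)
    weight_schedule: tuple[tuple[int, int], ...] = ((4, 3), (8, 2))
    base_weight: int = 1
    max_lna: int = 2
    max_candidates: int = 50

    def weight(self, pos_from_3prime: int) -> int:
        for limit, w in self.weight_schedule:
            if pos_from_3prime <= limit:
                return w
        return self.base_weight


@dataclass(frozen=True)
class WindowScore:
    window: tuple[int, int]            # 1-based inclusive alignment columns
    consensus: str                     # 5'->3' in alignment orientation
    target_coverage: float
    min_offtarget_mismatches: dict[str, int]
    weighted_discrimination: float
    degeneracy: int

    @property
    def exclusion_margin(self) -> int:
        """Worst case over off-target groups."""
        return min(self.min_offtarget_mismatches.values())


@dataclass(frozen=True)
class DesignCandidate:
    fwd_window: tuple[int, int]
    rev_window: tuple[int, int]
    fwd_primer: Primer
    rev_primer: Primer
    product_bp: int
    fwd_score: WindowScore
    rev_score: WindowScore

    @property
    def rank_key(self) -> tuple:
        margin = min(self.fwd_score.exclusion_margin, self.rev_score.exclusion_margin)
        coverage = min(self.fwd_score.target_coverage, self.rev_score.target_coverage)
        weighted = (
            self.fwd_score.weighted_discrimination
            + self.rev_score.weighted_discrimination
        )
        # ascending sort: best candidates first, leftmost-window tie-break
        return (-margin, -coverage, -weighted, self.fwd_window[0], self.rev_window[0])


class ConsensusError(CladePrimerError):
    """A consensus window is unusable (all-gap column, gap-majority column,
    or degeneracy above the cap)."""


def column_consensus(
    alignment: Alignment,
    rows: list[str] | None = None,
    degeneracy_cap: int | None = None,
    window: tuple[int, int] | None = None,
) -> str:
    """Minimal IUPAC consensus of the selected rows over a column window.

    Per column, the smallest IUPAC code covering every observed base. Gap
    characters are ignored while they occur in under half of the rows;
    gap-majority and all-gap columns make the window unusable. A degeneracy
    cap, when given, rejects windows whose consensus expands past it.
    """
    selected = (
        alignment.records if rows is None
        else tuple(alignment.row(r) for r in rows)
    )
    if not selected:
        raise ValueError("no rows selected for consensus")
    lo, hi = window if window is not None else (1, alignment.length)
    out = []
    for col in range(lo - 1, hi):
        bases = [r.sequence[col] for r in selected]
        gaps = sum(b == iupac.GAP for b in bases)
        if gaps == len(bases):
            raise ConsensusError(f"all-gap column {col + 1} among selected rows")
        if gaps * 2 >= len(bases):
            raise ConsensusError(f"gap-majority column {col + 1}: window unusable")
        observed: set[str] = set()
        for b in bases:
            if b != iupac.GAP:
                observed |= iupac.base_set(b)
        out.append(iupac.minimal_code(observed))
    consensus = "".join(out)
    if degeneracy_cap is not None and iupac.degeneracy(consensus) > degeneracy_cap:
        raise ConsensusError(
            f"consensus degeneracy {iupac.degeneracy(consensus)} exceeds cap"
        )
    return consensus


def _window_mismatches(
    consensus: str, row_seq: str, window: tuple[int, int], reverse_orientation: bool
) -> list[int]:
    """Mismatch positions (1-based from the primer 3' end) of one row
    against the window consensus.

    For a forward primer the 3' end is the window's last column; a reverse
    primer is the reverse complement of the consensus, so its 3' end is the
    window's first column.
    """
    lo, hi = window
    positions = []
    n = hi - lo + 1
    for k in range(n):
        if not iupac.codes_match(consensus[k], row_seq[lo - 1 + k]):
            pos3 = k + 1 if reverse_orientation else n - k
            positions.append(pos3)
    return sorted(positions)


def score_candidate_window(
    alignment: Alignment,
    window: tuple[int, int],
    targets: list[str],
    offtarget_groups: dict[str, list[str]],
    constraints: DesignConstraints | None = None,
    *,
    reverse_orientation: bool = False,
) -> WindowScore:
    """Score one alignment window as a primer site (reference semantics).

    Coverage is the fraction of target rows within the allowed mismatch
    count of the target consensus; each off-target group contributes the
    minimum mismatch count over its members; the weighted discrimination is
    the minimum over groups of the best member's 3'-weighted mismatch sum.
    """
    constraints = constraints or DesignConstraints()
    lo, hi = window
    n = hi - lo + 1
    if not constraints.min_primer_len <= n <= constraints.max_primer_len:
        raise ValueError(f"window length {n} outside primer length bounds")
    if not targets:
        raise ValueError("no target rows")
    consensus = column_consensus(
        alignment, targets, constraints.degeneracy_cap, window
    )
    covered = 0
    for t in targets:
        mm = _window_mismatches(
            consensus, alignment.row(t).sequence, window, reverse_orientation
        )
        if len(mm) <= constraints.coverage_max_mismatches:
            covered += 1
    coverage = covered / len(targets)

    min_offtarget: dict[str, int] = {}
    weighted = float("inf")
    for group, members in offtarget_groups.items():
        best: tuple[int, int] | None = None
        for m in members:
            mm = _window_mismatches(
                consensus, alignment.row(m).sequence, window, reverse_orientation
            )
            w = sum(constraints.weight(p) for p in mm)
            if best is None or (len(mm), w) < best:
                best = (len(mm), w)
        assert best is not None
        min_offtarget[group] = best[0]
        weighted = min(weighted, best[1])
    if not offtarget_groups:
        weighted = 0.0
    return WindowScore(
        window=window,
        consensus=consensus,
        target_coverage=coverage,
        min_offtarget_mismatches=min_offtarget,
        weighted_discrimination=weighted,
        degeneracy=iupac.degeneracy(consensus),
    )


# --- fast exhaustive scan -------------------------------------------------


class _ScanTables:
    """Per-column precomputation making each window score O(rows)."""

    def __init__(
        self,
        alignment: Alignment,
        targets: list[str],
        offtargets: dict[str, list[str]],
        constraints: DesignConstraints,
    ) -> None:
        self.constraints = constraints
        self.offtargets = offtargets
        self.targets = targets
        L = alignment.length
        seqs = {r.id: r.sequence for r in alignment}
        self.usable = np.ones(L, dtype=bool)
        self.card = np.ones(L, dtype=np.int64)
        cons_chars: list[str] = []
        n_t = len(targets)
        for col in range(L):
            observed: set[str] = set()
            gaps = 0
            for t in targets:
                b = seqs[t][col]
                if b == iupac.GAP:
                    gaps += 1
                else:
                    observed |= iupac.base_set(b)
            if gaps * 2 >= n_t or not observed:
                self.usable[col] = False
                cons_chars.append("N")
                continue
            code = iupac.minimal_code(observed)
            cons_chars.append(code)
            self.card[col] = len(observed)
        self.consensus = "".join(cons_chars)
        self.bad_prefix = np.concatenate([[0], np.cumsum(~self.usable)])
        # mismatch indicator prefix sums per row of interest
        self.mis_prefix: dict[str, np.ndarray] = {}
        rows_needed = list(targets) + [m for ms in offtargets.values() for m in ms]
        for rid in rows_needed:
            row = seqs[rid]
            ind = np.fromiter(
                (
                    1 if (self.usable[c] and not iupac.codes_match(self.consensus[c], row[c]))
                    else 0
                    for c in range(L)
                ),
                dtype=np.int64,
                count=L,
            )
            self.mis_prefix[rid] = np.concatenate([[0], np.cumsum(ind)])
        # +1-weight bands derived from the schedule (innermost first)
        bands = []
        schedule = sorted(constraints.weight_schedule)
        for k, (limit, w) in enumerate(schedule):
            nxt = schedule[k + 1][1] if k + 1 < len(schedule) else constraints.base_weight
            bands.append((limit, w - nxt))
        self.bands = bands

    def _count(self, rid: str, lo: int, hi: int) -> int:
        p = self.mis_prefix[rid]
        return int(p[hi] - p[lo - 1])

    def _weighted(self, rid: str, lo: int, hi: int, reverse_orientation: bool) -> int:
        base = self.constraints.base_weight * self._count(rid, lo, hi)
        extra = 0
        for limit, inc in self.bands:
            if reverse_orientation:
                b_lo, b_hi = lo, min(hi, lo + limit - 1)
            else:
                b_lo, b_hi = max(lo, hi - limit + 1), hi
            extra += inc * self._count(rid, b_lo, b_hi)
        return base + extra

    def window_ok(self, lo: int, hi: int) -> bool:
        if self.bad_prefix[hi] - self.bad_prefix[lo - 1] > 0:
            return False
        return int(np.prod(self.card[lo - 1:hi])) <= self.constraints.degeneracy_cap

    def score(self, lo: int, hi: int, reverse_orientation: bool) -> WindowScore:
        c = self.constraints
        covered = sum(
            1 for t in self.targets
            if self._count(t, lo, hi) <= c.coverage_max_mismatches
        )
        min_off: dict[str, int] = {}
        weighted = float("inf")
        for group, members in self.offtargets.items():
            best: tuple[int, int] | None = None
            for m in members:
                pair = (
                    self._count(m, lo, hi),
                    self._weighted(m, lo, hi, reverse_orientation),
                )
                if best is None or pair < best:
                    best = pair
            assert best is not None
            min_off[group] = best[0]
            weighted = min(weighted, best[1])
        if not self.offtargets:
            weighted = 0.0
        return WindowScore(
            window=(lo, hi),
            consensus=self.consensus[lo - 1:hi],
            target_coverage=covered / len(self.targets),
            min_offtarget_mismatches=min_off,
            weighted_discrimination=weighted,
            degeneracy=int(np.prod(self.card[lo - 1:hi])),
        )


def design_primer_pairs(
    alignment: Alignment,
    taxa: TaxonMap,
    constraints: DesignConstraints | None = None,
) -> list[DesignCandidate]:
    """Exhaustive scan for discriminative forward/reverse window pairs.

    Returns up to `max_candidates` candidates ranked by (worst-case
    exclusion margin, coverage, 3'-weighted discrimination), ties broken by
    leftmost forward then reverse window start. An empty list means no
    window pair satisfied the constraints.
    """
    constraints = constraints or DesignConstraints()
    targets = [i for i in alignment.ids if i in taxa and taxa[i].role == "target"]
    offtarget_ids = [
        i for i in alignment.ids if i in taxa and taxa[i].role == "excluded"
    ]
    if not targets or not offtarget_ids:
        raise ValueError("need at least one target and one excluded row")
    offtargets: dict[str, list[str]] = {}
    for i in offtarget_ids:
        offtargets.setdefault(taxa.group_of(i), []).append(i)

    tables = _ScanTables(alignment, targets, offtargets, constraints)

    def usable_windows(reverse_orientation: bool) -> list[WindowScore]:
        out = []
        for length in range(constraints.min_primer_len, constraints.max_primer_len + 1):
            for lo in range(1, alignment.length - length + 2):
                hi = lo + length - 1
                if not tables.window_ok(lo, hi):
                    continue
                score = tables.score(lo, hi, reverse_orientation)
                if score.target_coverage >= constraints.min_target_coverage:
                    out.append(score)
        return out

    fwd_scores = usable_windows(False)
    rev_scores = usable_windows(True)
    rev_by_end: dict[int, list[WindowScore]] = {}
    for rs in rev_scores:
        rev_by_end.setdefault(rs.window[1], []).append(rs)

    scored_pairs: list[tuple[tuple, WindowScore, WindowScore, int]] = []
    for fs in fwd_scores:
        f_lo, f_hi = fs.window
        for end in range(
            f_lo + constraints.min_product_bp - 1,
            min(alignment.length, f_lo + constraints.max_product_bp - 1) + 1,
        ):
            for rs in rev_by_end.get(end, ()):
                if rs.window[0] <= f_hi:
                    continue
                product = end - f_lo + 1
                margin = min(fs.exclusion_margin, rs.exclusion_margin)
                coverage = min(fs.target_coverage, rs.target_coverage)
                weighted = fs.weighted_discrimination + rs.weighted_discrimination
                key = (-margin, -coverage, -weighted, f_lo, rs.window[0])
                scored_pairs.append((key, fs, rs, product))
    scored_pairs.sort(key=lambda t: t[0])

    candidates = []
    for _, fs, rs, product in scored_pairs[: constraints.max_candidates]:
        candidates.append(
            DesignCandidate(
                fwd_window=fs.window,
                rev_window=rs.window,
                fwd_primer=Primer(
                    name=f"fwd_{fs.window[0]}_{fs.window[1]}",
                    core=fs.consensus,
                    orientation="forward",
                ),
                rev_primer=Primer(
                    name=f"rev_{rs.window[0]}_{rs.window[1]}",
                    core=iupac.reverse_complement(rs.consensus),
                    orientation="reverse",
                ),
                product_bp=product,
                fwd_score=fs,
                rev_score=rs,
            )
        )
    return candidates


def _plant_discriminating_positions(
    score: WindowScore,
    alignment: Alignment,
    plant_rows: list[str],
    reverse_orientation: bool,
) -> set[int]:
    """Primer positions (1-based from 3') where ALL plant rows mismatch."""
    if not plant_rows:
        return set()
    common: set[int] | None = None
    for p in plant_rows:
        mm = set(
            _window_mismatches(
                score.consensus, alignment.row(p).sequence, score.window,
                reverse_orientation,
            )
        )
        common = mm if common is None else (common & mm)
    return common or set()


def suggest_modifications(
    candidate: DesignCandidate,
    alignment: Alignment,
    taxa: TaxonMap,
    constraints: DesignConstraints | None = None,
    plant_phyla: frozenset[str] = PLANT_PHYLA,
) -> DesignCandidate:
    """Propose LNA positions on both primers of a candidate.

    A position qualifies when every plant row mismatches the consensus
    there; up to `max_lna` positions are locked per primer, highest
    3'-proximity weight first (position closest to the 3' end wins ties).
    Candidates with no qualifying position come back unmodified.
    """
    constraints = constraints or DesignConstraints()
    plant_rows = [
        i for i in alignment.ids
        if i in taxa and taxa[i].phylum in plant_phyla
    ]

    def lna_for(score: WindowScore, reverse_orientation: bool) -> frozenset[int]:
        qualifying = _plant_discriminating_positions(
            score, alignment, plant_rows, reverse_orientation
        )
        ranked = sorted(
            qualifying, key=lambda p: (-constraints.weight(p), p)
        )[: constraints.max_lna]
        n = score.window[1] - score.window[0] + 1
        # positions-from-3' -> 1-based 5' positions on the primer itself
        return frozenset(n - p + 1 for p in ranked)

    fwd_lna = lna_for(candidate.fwd_score, False)
    rev_lna = lna_for(candidate.rev_score, True)
    return replace(
        candidate,
        fwd_primer=replace(candidate.fwd_primer, lna_positions=fwd_lna),
        rev_primer=replace(candidate.rev_primer, lna_positions=rev_lna),
    )
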