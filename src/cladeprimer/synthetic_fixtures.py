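"""Synthetic 18S-like panels with planted primer windows and clade-structured
mismatch patterns.

No accessions accompany the study this toolkit operationalizes, so every
consumer module is exercised against generated panels whose primer-window
mismatch structure mirrors the per-clade pattern reported for the basal
Mucoromycota primer set: target classes (Glomeromycetes, Mortierellomycetes,
Endogonomycetes, Umbelopsidomycetes) carry perfect primer windows; plants
carry 2-3 mismatches per window; Mucoromycetes carry 2-3 in the forward and
2-5 in the reverse window; Ascomycota and Basidiomycota carry 1-2 mismatches
placed inside the 3'-terminal clamp, the configuration under which a single
mismatch suppresses extension.

Evolution is substitution-only inside a fixed-length backbone: every group
shares coordinates, so the reference panel is trivially its own alignment
and no aligner enters the test loop. Sequence generation is bit-reproducible
under a fixed seed, and every panel ships a PanelTruth that can be re-derived
by directly recounting window mismatches on the emitted sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import iupac
from .errors import FixtureConfigError
from .primer_model import Primer, builtin_primers, expand_degenerate
from .seq_io import Alignment, SequenceRecord, TaxonEntry, TaxonMap
from .specificity_engine import AmplificationRules

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GroupSpec:
    """Mismatch recipe for one taxon group.

    Mismatch counts are drawn uniformly from the inclusive ranges; the
    position policy controls where they land relative to the primer 3' end:
    ``uniform`` anywhere, ``clamp_biased`` with at least one inside the
    clamp, ``clamp_avoiding`` all outside the clamp, ``edge_anchored`` with
    one at each terminal base of the window (the remainder uniform inside).
    """

    name: str
    phylum: str
    role: str
    n_sequences: int
    fwd_mismatches: tuple[int, int] = (0, 0)
    rev_mismatches: tuple[int, int] = (0, 0)
    position_policy: str = "uniform"


@dataclass(frozen=True)
class PanelConfig:
    groups: tuple[GroupSpec, ...]
    backbone_length: int = 1700
    fwd_start: int = 639              # 1-based plant position of the forward window
    product_bp: int = 260             # amplicon length including both footprints
    within_divergence: float = 0.01
    between_divergence: float = 0.05
    clamp_window: int = 4
    seed: int = 0
    fwd_primer: Primer | None = None  # None -> shipped clade-specific pair
    rev_primer: Primer | None = None
    #: columns (1-based) forced to carry all four bases across target rows;
    #: placed flanking the planted windows they make any window that leaks
    #: past a planted edge exceed the consensus degeneracy cap, which is what
    #: makes the planted windows the unique design optimum
    spoiler_columns: tuple[int, ...] = ()

    def resolved_primers(self) -> tuple[Primer, Primer]:
        if self.fwd_primer is not None and self.rev_primer is not None:
            return self.fwd_primer, self.rev_primer
        table = builtin_primers()
        return table["BM0639-5LNA"], table["BM0853-3LNA"]

    def windows(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """((fwd_start, fwd_end), (rev_start, rev_end)), 1-based inclusive."""
        fwd, rev = self.resolved_primers()
        fwd_end = self.fwd_start + len(fwd) - 1
        rev_end = self.fwd_start + self.product_bp - 1
        rev_start = rev_end - len(rev) + 1
        return (self.fwd_start, fwd_end), (rev_start, rev_end)

    def validate(self) -> None:
        (f0, f1), (r0, r1) = self.windows()
        fwd, rev = self.resolved_primers()
        if f0 < 1 or r1 > self.backbone_length:
            raise FixtureConfigError("primer windows fall outside the backbone")
        if f1 >= r0:
            raise FixtureConfigError(
                "product length inconsistent with primer footprints"
            )
        if not 0 <= self.within_divergence <= 0.75 or not 0 <= self.between_divergence <= 0.75:
            raise FixtureConfigError("divergence rates must lie in [0, 0.75]")
        for col in self.spoiler_columns:
            if not 1 <= col <= self.backbone_length:
                raise FixtureConfigError(f"spoiler column {col} outside backbone")
            if f0 <= col <= f1 or r0 <= col <= r1:
                raise FixtureConfigError(f"spoiler column {col} inside a primer window")
        for g in self.groups:
            for rng_, primer in ((g.fwd_mismatches, fwd), (g.rev_mismatches, rev)):
                lo, hi = rng_
                if not 0 <= lo <= hi <= len(primer):
                    raise FixtureConfigError(
                        f"group {g.name}: mismatch range {rng_} infeasible for a "
                        f"{len(primer)}-nt window"
                    )


@dataclass(frozen=True)
class SequenceTruth:
    group: str
    role: str
    fwd_mismatch_count: int
    rev_mismatch_count: int
    fwd_positions_from_3prime: tuple[int, ...]
    rev_positions_from_3prime: tuple[int, ...]
    expected_amplify: bool


@dataclass(frozen=True)
class PanelTruth:
    fwd_window: tuple[int, int]
    rev_window: tuple[int, int]
    product_bp: int
    per_sequence: dict[str, SequenceTruth] = field(default_factory=dict)


@dataclass(frozen=True)
class CloneTruth:
    generating_class: str
    source_template: str
    n_errors: int


def table2_panel_config(seed: int = 0) -> PanelConfig:
    """The shipped 13-template panel shaped after the wet-lab template set:
    five target-class templates, two Mucoromycetes, two Ascomycota, two
    Basidiomycota, and two plants."""
    groups = (
        GroupSpec("Glomeromycetes", "Mucoromycota", "target", 1),
        GroupSpec("Mortierellomycetes", "Mucoromycota", "target", 1),
        GroupSpec("Endogonomycetes", "Mucoromycota", "target", 2),
        GroupSpec("Umbelopsidomycetes", "Mucoromycota", "target", 1),
        GroupSpec("Mucoromycetes", "Mucoromycota", "excluded", 2,
                  fwd_mismatches=(2, 3), rev_mismatches=(2, 5)),
        GroupSpec("Saccharomycetes", "Ascomycota", "excluded", 1,
                  fwd_mismatches=(1, 2), rev_mismatches=(1, 2),
                  position_policy="clamp_biased"),
        GroupSpec("Sordariomycetes", "Ascomycota", "excluded", 1,
                  fwd_mismatches=(1, 2), rev_mismatches=(1, 2),
                  position_policy="clamp_biased"),
        GroupSpec("Agaricomycetes", "Basidiomycota", "excluded", 1,
                  fwd_mismatches=(1, 2), rev_mismatches=(1, 2),
                  position_policy="clamp_biased"),
        GroupSpec("Ustilaginomycetes", "Basidiomycota", "excluded", 1,
                  fwd_mismatches=(1, 2), rev_mismatches=(1, 2),
                  position_policy="clamp_biased"),
        GroupSpec("Magnoliopsida", "Tracheophyta", "excluded", 1,
                  fwd_mismatches=(2, 3), rev_mismatches=(2, 3)),
        GroupSpec("Liliopsida", "Tracheophyta", "excluded", 1,
                  fwd_mismatches=(2, 3), rev_mismatches=(2, 3)),
    )
    return PanelConfig(groups=groups, seed=seed)


def design_panel_config(seed: int = 0) -> PanelConfig:
    """Panel for primer-design recovery.

    The planted windows sit at the alignment edges (the alignment is the
    amplicon region itself), off-target groups carry edge-anchored mismatch
    blocks, both planted primers contain a degenerate M column, and spoiler
    columns flank the interior window edges — together these make the
    planted window pair the unique optimum of the design ranking under the
    default constraints: extending past a window edge exceeds the degeneracy
    cap, shrinking drops an edge-anchored off-target mismatch.
    """
    from .primer_model import parse_primer_spec

    fwd = parse_primer_spec(
        "GTTAAAAAGCTMGTAGTTGAATTT", name="design_truth_fwd", orientation="forward"
    )
    rev = parse_primer_spec(
        "CAACTATCCCTATTMATCATTAC", name="design_truth_rev", orientation="reverse"
    )
    groups = (
        GroupSpec("Glomeromycetes", "Mucoromycota", "target", 2),
        GroupSpec("Mortierellomycetes", "Mucoromycota", "target", 2),
        GroupSpec("Endogonomycetes", "Mucoromycota", "target", 2),
        GroupSpec("Mucoromycetes", "Mucoromycota", "excluded", 2,
                  fwd_mismatches=(4, 5), rev_mismatches=(4, 6),
                  position_policy="edge_anchored"),
        GroupSpec("Magnoliopsida", "Tracheophyta", "excluded", 2,
                  fwd_mismatches=(4, 5), rev_mismatches=(4, 5),
                  position_policy="edge_anchored"),
    )
    return PanelConfig(
        groups=groups,
        backbone_length=260,
        fwd_start=1,
        product_bp=260,
        within_divergence=0.01,
        between_divergence=0.03,
        seed=seed,
        fwd_primer=fwd,
        rev_primer=rev,
        spoiler_columns=(25, 237),   # fwd_end + 1 and rev_start - 1
    )


def classification_panel_config(seed: int = 0) -> PanelConfig:
    """Panel for clone-classification fixtures: several references per
    target class at clear between-class divergence."""
    groups = (
        GroupSpec("Glomeromycetes", "Mucoromycota", "target", 3),
        GroupSpec("Mortierellomycetes", "Mucoromycota", "target", 3),
        GroupSpec("Endogonomycetes", "Mucoromycota", "target", 3),
        GroupSpec("Agaricomycetes", "Basidiomycota", "outgroup", 1,
                  fwd_mismatches=(1, 2), rev_mismatches=(1, 2),
                  position_policy="clamp_biased"),
    )
    return PanelConfig(
        groups=groups,
        backbone_length=900,
        fwd_start=301,
        within_divergence=0.015,
        between_divergence=0.06,
        seed=seed,
    )


# --- generation internals -------------------------------------------------


def _mutate(rng: np.random.Generator, arr: np.ndarray, rate: float,
            protect: np.ndarray) -> np.ndarray:
    """Substitute bases at `rate` outside protected positions."""
    out = arr.copy()
    hit = (rng.random(arr.size) < rate) & ~protect
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out


def _draw_positions(
    rng: np.random.Generator, k: int, length: int, policy: str, clamp: int
) -> list[int]:
    """Choose k distinct mismatch positions (1-based from the 3' end)."""
    if k == 0:
        return []
    if k > length:
        raise FixtureConfigError(f"cannot plant {k} mismatches in {length} nt")
    all_pos = list(range(1, length + 1))
    if policy == "uniform":
        return sorted(rng.choice(all_pos, size=k, replace=False).tolist())
    if policy == "clamp_avoiding":
        pool = [p for p in all_pos if p > clamp]
        if k > len(pool):
            raise FixtureConfigError("too many clamp-avoiding mismatches")
        return sorted(rng.choice(pool, size=k, replace=False).tolist())
    if policy == "clamp_biased":
        first = int(rng.integers(1, clamp + 1))
        rest_pool = [p for p in all_pos if p != first]
        rest = rng.choice(rest_pool, size=k - 1, replace=False).tolist() if k > 1 else []
        return sorted([first, *rest])
    if policy == "edge_anchored":
        fixed = [1, length] if k >= 2 else [1]
        pool = [p for p in all_pos if p not in fixed]
        extra = (
            rng.choice(pool, size=k - len(fixed), replace=False).tolist()
            if k > len(fixed) else []
        )
        return sorted([*fixed, *extra])
    raise FixtureConfigError(f"unknown position policy {policy!r}")


def _plant_window(
    rng: np.random.Generator,
    seq: np.ndarray,
    primer: Primer,
    window: tuple[int, int],
    orientation: str,
    n_mismatches: int,
    policy: str,
    clamp: int,
    expansion_index: int = 0,
) -> tuple[int, ...]:
    """Write a primer footprint with exactly `n_mismatches` planted
    mismatches into `seq` (plus strand); returns positions from the primer's
    3' end. Degenerate expansions are cycled across rows so every variant a
    mixed base covers actually occurs in the panel."""
    expansions = expand_degenerate(primer)
    site = list(expansions[expansion_index % len(expansions)])  # primer 5'->3'
    k = len(site)
    positions = _draw_positions(rng, n_mismatches, k, policy, clamp)
    for p in positions:
        idx = k - p  # 0-based index from primer 5' end
        allowed = sorted(set("ACGT") - iupac.base_set(primer.core[idx]))
        if not allowed:
            raise FixtureConfigError(
                f"primer {primer.name} position {idx + 1} is N; cannot mismatch"
            )
        site[idx] = allowed[rng.integers(0, len(allowed))]
    footprint = "".join(site)
    if orientation == "reverse":
        footprint = iupac.reverse_complement(footprint)
    start0 = window[0] - 1
    seq[start0:start0 + k] = list(footprint)
    return tuple(positions)


def _expected_amplify(
    truth_fwd: tuple[int, ...], truth_rev: tuple[int, ...],
    rules: AmplificationRules,
) -> bool:
    for positions in (truth_fwd, truth_rev):
        if len(positions) > rules.max_mismatches_per_primer:
            return False
        clamp_mm = sum(1 for p in positions if p <= rules.clamp_window)
        if clamp_mm > rules.clamp_max_mismatches:
            return False
    return True


def _generate(
    config: PanelConfig, rules: AmplificationRules
) -> tuple[list[SequenceRecord], TaxonMap, PanelTruth]:
    config.validate()
    fwd, rev = config.resolved_primers()
    fwd_window, rev_window = config.windows()
    rng = np.random.default_rng(config.seed)

    protect = np.zeros(config.backbone_length, dtype=bool)
    for (a, b) in (fwd_window, rev_window):
        protect[a - 1:b] = True
    for col in config.spoiler_columns:
        protect[col - 1] = True

    backbone = _BASES[rng.integers(0, 4, size=config.backbone_length)]
    records: list[SequenceRecord] = []
    taxa = TaxonMap()
    truth = PanelTruth(
        fwd_window=fwd_window, rev_window=rev_window, product_bp=config.product_bp
    )

    row_counter = 0
    target_counter = 0
    for group in config.groups:
        group_backbone = _mutate(rng, backbone, config.between_divergence, protect)
        for k in range(group.n_sequences):
            seq = _mutate(rng, group_backbone, config.within_divergence, protect)
            n_fwd = int(rng.integers(group.fwd_mismatches[0], group.fwd_mismatches[1] + 1))
            n_rev = int(rng.integers(group.rev_mismatches[0], group.rev_mismatches[1] + 1))
            fwd_pos = _plant_window(
                rng, seq, fwd, fwd_window, "forward", n_fwd,
                group.position_policy, config.clamp_window, row_counter,
            )
            rev_pos = _plant_window(
                rng, seq, rev, rev_window, "reverse", n_rev,
                group.position_policy, config.clamp_window, row_counter,
            )
            if group.role == "target" and config.spoiler_columns:
                for col in config.spoiler_columns:
                    seq[col - 1] = _BASES[target_counter % 4]
            row_counter += 1
            if group.role == "target":
                target_counter += 1
            seq_id = f"{group.name}_{k + 1}"
            records.append(SequenceRecord(id=seq_id, sequence="".join(seq)))
            taxa.entries[seq_id] = TaxonEntry(
                phylum=group.phylum, klass=group.name, role=group.role
            )
            truth.per_sequence[seq_id] = SequenceTruth(
                group=group.name,
                role=group.role,
                fwd_mismatch_count=n_fwd,
                rev_mismatch_count=n_rev,
                fwd_positions_from_3prime=fwd_pos,
                rev_positions_from_3prime=rev_pos,
                expected_amplify=_expected_amplify(fwd_pos, rev_pos, rules),
            )
    return records, taxa, truth


def generate_reference_panel(
    config: PanelConfig | None = None,
    rules: AmplificationRules | None = None,
) -> tuple[Alignment, TaxonMap, PanelTruth]:
    """Aligned reference panel (substitution-only evolution, so the rows are
    already in common coordinates)."""
    config = config or table2_panel_config()
    records, taxa, truth = _generate(config, rules or AmplificationRules())
    return Alignment(tuple(records)), taxa, truth


def generate_pcr_templates(
    config: PanelConfig | None = None,
    rules: AmplificationRules | None = None,
) -> tuple[list[SequenceRecord], TaxonMap, PanelTruth]:
    """Unaligned template panel for in-silico PCR (same generator; returned
    as plain records because templates are conceptually unaligned)."""
    config = config or table2_panel_config()
    return _generate(config, rules or AmplificationRules())


def amplicon_region(
    record: SequenceRecord, truth: PanelTruth
) -> str:
    """The planted amplicon substring (both primer footprints included)."""
    start = truth.fwd_window[0] - 1
    end = truth.rev_window[1]
    return record.sequence[start:end]


def simulate_vesicle_clones(
    panel: list[SequenceRecord] | Alignment,
    taxa: TaxonMap,
    truth: PanelTruth,
    mixture: dict[str, float],
    n_clones: int = 8,
    error_rate: float = 0.005,
    seed: int = 0,
) -> tuple[list[SequenceRecord], dict[str, CloneTruth]]:
    """Simulate cloned amplicon reads from a single vesicle.

    Each clone picks a generating class by the mixture weights, then a
    template of that class, takes its planted amplicon region, and applies a
    uniform per-base error (PCR + Sanger read noise). The 5-8 clones-per-
    sample regime of single-vesicle typing is the intended scale.
    """
    if not mixture:
        raise ValueError("empty mixture")
    total = sum(mixture.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixture weights must sum to 1 (got {total:g})")
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    records = list(panel.records) if isinstance(panel, Alignment) else list(panel)
    by_class: dict[str, list[SequenceRecord]] = {}
    for rec in records:
        if rec.id in taxa:
            by_class.setdefault(taxa[rec.id].klass, []).append(rec)
    missing = set(mixture) - set(by_class)
    if missing:
        raise ValueError(f"mixture classes absent from panel: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    classes = sorted(mixture)
    weights = np.array([mixture[c] for c in classes])
    clones: list[SequenceRecord] = []
    clone_truth: dict[str, CloneTruth] = {}
    for i in range(n_clones):
        cls = classes[rng.choice(len(classes), p=weights)]
        template = by_class[cls][rng.integers(0, len(by_class[cls]))]
        region = list(amplicon_region(template, truth))
        n_err = 0
        for j in range(len(region)):
            if rng.random() < error_rate:
                choices = [b for b in "ACGT" if b != region[j]]
                region[j] = choices[rng.integers(0, 3)]
                n_err += 1
        clone_id = f"clone_{i + 1}"
        clones.append(SequenceRecord(id=clone_id, sequence="".join(region)))
        clone_truth[clone_id] = CloneTruth(
            generating_class=cls, source_template=template.id, n_errors=n_err
        )
    return clones, clone_truth


def reference_amplicon_alignment(
    panel: Alignment | list[SequenceRecord], truth: PanelTruth,
    taxa: TaxonMap | None = None, roles: tuple[str, ...] = ("target",),
) -> Alignment:
    """Alignment restricted to the planted amplicon region (and, when a
    taxon map is given, to rows with the listed roles) — the reference set a
    clone classifier compares against."""
    records = list(panel.records) if isinstance(panel, Alignment) else list(panel)
    rows = []
    for rec in records:
        if taxa is not None and (rec.id not in taxa or taxa[rec.id].role not in roles):
            continue
        rows.append(SequenceRecord(rec.id, amplicon_region(rec, truth)))
    return Alignment(tuple(rows))
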