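"""In-silico PCR: binding sites, amplicon prediction, mismatch profiles.

The engine answers the two questions a taxon-specific primer set is designed
around: *where* does each primer sit on a template and with how many
mismatches, and *which* templates would yield a product under a mismatch
tolerance rule. Mismatch counting is IUPAC-set based (disjoint sets =
mismatch); mismatch positions are always reported 1-based from the primer's
3' end, because mismatches close to the 3' terminus are what suppress
polymerase extension.

Amplification rules are deliberately explicit configuration: wet-lab PCR has
no published mismatch threshold, so the defaults (at most one mismatch per
primer, none inside the 4-base 3' clamp, product between 80 and 2000 bp)
are a conventional stringent setting and every knob is exposed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from statistics import median

from . import iupac
from .errors import EmptyPanelError, TemplateTooShortError
from .primer_model import Primer
from .seq_io import Alignment, SequenceRecord, TaxonMap

__all__ = [
    "AmplificationRules",
    "BindingSite",
    "AmpliconPrediction",
    "MismatchProfile",
    "iupac_mismatch_count",
    "find_binding_sites",
    "best_site",
    "predict_amplicons",
    "taxon_mismatch_profile",
    "specificity_table",
]


@dataclass(frozen=True)
class AmplificationRules:
    """Thresholds deciding whether a primer pair yields a product."""

    max_mismatches_per_primer: int = 1
    clamp_window: int = 4          # 3'-terminal bases where no mismatch is tolerated
    clamp_max_mismatches: int = 0
    min_product_bp: int = 80
    max_product_bp: int = 2000

    def __post_init__(self) -> None:
        if self.min_product_bp >= self.max_product_bp:
            raise ValueError("min_product_bp must be < max_product_bp")
        if min(self.max_mismatches_per_primer, self.clamp_window,
               self.clamp_max_mismatches, self.min_product_bp) < 0:
            raise ValueError("rule fields must be non-negative")

    def site_passes(self, site: "BindingSite") -> bool:
        if site.mismatch_count > self.max_mismatches_per_primer:
            return False
        clamp_mm = sum(
            1 for p in site.mismatch_positions_from_3prime if p <= self.clamp_window
        )
        return clamp_mm <= self.clamp_max_mismatches


@dataclass(frozen=True)
class BindingSite:
    """A primer footprint on the template's plus strand.

    Coordinates are 1-based inclusive. Reverse-orientation primers are
    located by scanning with the reverse-complemented core, so their
    3'-terminal base corresponds to `start`.
    """

    template_id: str
    strand: str                      # '+' (forward primer) or '-' (reverse primer)
    start: int
    end: int
    mismatch_count: int
    mismatch_positions_from_3prime: tuple[int, ...]
    three_prime_clamp_ok: bool

    def __post_init__(self) -> None:
        assert self.mismatch_count == len(self.mismatch_positions_from_3prime)


@dataclass(frozen=True)
class AmpliconPrediction:
    template_id: str
    fwd_site: BindingSite
    rev_site: BindingSite
    product_start: int
    product_end: int
    length_bp: int                   # includes both primer footprints
    adaptor_linked_length_bp: int

    def __post_init__(self) -> None:
        assert self.product_start < self.product_end
        assert self.length_bp == self.product_end - self.product_start + 1


@dataclass(frozen=True)
class ProfileRow:
    group: str
    role: str
    n_sequences: int
    fwd_min: int
    fwd_median: float
    fwd_max: int
    rev_min: int
    rev_median: float
    rev_max: int
    n_clamp_mismatch: int            # sequences with any mismatch inside a 3' clamp


@dataclass(frozen=True)
class MismatchProfile:
    rows: tuple[ProfileRow, ...]
    clamp_window: int

    def row(self, group: str) -> ProfileRow:
        for r in self.rows:
            if r.group == group:
                return r
        raise KeyError(group)

    def to_tsv(self) -> str:
        buf = io.StringIO()
        buf.write(
            "group\trole\tn\tfwd_min\tfwd_median\tfwd_max\t"
            "rev_min\trev_median\trev_max\tn_clamp_mismatch\n"
        )
        for r in self.rows:
            buf.write(
                f"{r.group}\t{r.role}\t{r.n_sequences}\t{r.fwd_min}\t"
                f"{r.fwd_median:g}\t{r.fwd_max}\t{r.rev_min}\t{r.rev_median:g}\t"
                f"{r.rev_max}\t{r.n_clamp_mismatch}\n"
            )
        return buf.getvalue()


def iupac_mismatch_count(
    primer_core: str, site: str, *, gap_policy: str = "mismatch"
) -> tuple[int, tuple[int, ...]]:
    """Count mismatching positions between a primer core and a same-length
    site, positions reported 1-based from the primer's 3' end.

    A position mismatches iff the IUPAC base-sets are disjoint. A gap in the
    site is a mismatch under ``gap_policy='mismatch'``; under ``'drop'`` the
    caller is expected to have removed gap columns already and a remaining
    gap still counts as a mismatch.
    """
    if len(primer_core) != len(site):
        raise ValueError(
            f"length mismatch: primer {len(primer_core)} vs site {len(site)}"
        )
    n = len(primer_core)
    positions = tuple(
        n - i for i in range(n) if not iupac.codes_match(primer_core[i], site[i])
    )
    return len(positions), tuple(sorted(positions))


def _scan_core(
    core: str,
    primer_is_reversed: bool,
    template: SequenceRecord,
    max_mm: int,
    clamp_window: int,
) -> list[BindingSite]:
    seq = template.sequence
    k = len(core)
    if len(seq) < k:
        raise TemplateTooShortError(
            f"template {template.id} ({len(seq)} nt) shorter than primer ({k} nt)"
        )
    sites = []
    for start0 in range(len(seq) - k + 1):
        window = seq[start0:start0 + k]
        count, pos3 = iupac_mismatch_count(core, window)
        if primer_is_reversed:
            # core is the reverse complement of the primer: primer 3' pairs
            # with the window's first base, so flip the position convention
            count = count
            pos3 = tuple(sorted(k - p + 1 for p in pos3))
        if count <= max_mm:
            clamp_ok = all(p > clamp_window for p in pos3)
            sites.append(
                BindingSite(
                    template_id=template.id,
                    strand="-" if primer_is_reversed else "+",
                    start=start0 + 1,
                    end=start0 + k,
                    mismatch_count=count,
                    mismatch_positions_from_3prime=pos3,
                    three_prime_clamp_ok=clamp_ok,
                )
            )
    sites.sort(key=lambda s: (s.mismatch_count, s.start))
    return sites


def find_binding_sites(
    primer: Primer,
    template: SequenceRecord,
    max_mm: int = 3,
    clamp_window: int = 4,
) -> list[BindingSite]:
    """All plus-strand windows where the primer binds with <= max_mm
    mismatches, sorted by (mismatch_count, start).

    Forward primers are scanned as-is; reverse primers are scanned as their
    reverse complement (their footprint on the plus strand).
    """
    if primer.orientation == "reverse":
        core = iupac.reverse_complement(primer.core)
        return _scan_core(core, True, template, max_mm, clamp_window)
    return _scan_core(primer.core, False, template, max_mm, clamp_window)


def best_site(
    primer: Primer, template: SequenceRecord, max_mm: int = 10
) -> BindingSite | None:
    sites = find_binding_sites(primer, template, max_mm=max_mm)
    return sites[0] if sites else None


def predict_amplicons(
    fwd: Primer,
    rev: Primer,
    template: SequenceRecord,
    rules: AmplificationRules | None = None,
) -> list[AmpliconPrediction]:
    """Predicted products: every passing forward site paired with every
    downstream passing reverse site within the length bounds. An empty list
    means "no amplification"."""
    rules = rules or AmplificationRules()
    fwd_sites = [
        s
        for s in find_binding_sites(
            fwd, template, rules.max_mismatches_per_primer, rules.clamp_window
        )
        if rules.site_passes(s)
    ]
    rev_sites = [
        s
        for s in find_binding_sites(
            rev, template, rules.max_mismatches_per_primer, rules.clamp_window
        )
        if rules.site_passes(s)
    ]
    out = []
    for fs in fwd_sites:
        for rs in rev_sites:
            if rs.start <= fs.end:
                continue
            length = rs.end - fs.start + 1
            if not rules.min_product_bp <= length <= rules.max_product_bp:
                continue
            out.append(
                AmpliconPrediction(
                    template_id=template.id,
                    fwd_site=fs,
                    rev_site=rs,
                    product_start=fs.start,
                    product_end=rs.end,
                    length_bp=length,
                    adaptor_linked_length_bp=length + len(fwd.adaptor) + len(rev.adaptor),
                )
            )
    out.sort(key=lambda a: (a.product_start, a.product_end))
    return out


_ROLE_ORDER = {"target": 0, "excluded": 1, "outgroup": 2}


def _degap_record(record: SequenceRecord) -> SequenceRecord:
    if "-" not in record.sequence:
        return record
    return SequenceRecord(
        id=record.id,
        sequence=record.sequence.replace("-", ""),
        description=record.description,
    )


def taxon_mismatch_profile(
    fwd: Primer,
    rev: Primer,
    panel: list[SequenceRecord] | Alignment,
    taxa: TaxonMap,
    *,
    group_key: str = "class",
    clamp_window: int = 4,
    max_mm_scan: int = 10,
    gap_policy: str = "drop",
) -> MismatchProfile:
    """Per-taxon-group summary of best-site mismatch counts for each primer.

    Aligned panels are degapped per sequence before scanning when
    ``gap_policy='drop'`` (the default); ``'mismatch'`` retains gaps so a gap
    column inside a primer window counts as a mismatch. Rows are ordered by
    role (target, excluded, outgroup) then group name.
    """
    records = list(panel.records) if isinstance(panel, Alignment) else list(panel)
    if not records:
        raise EmptyPanelError("no sequences in panel")
    if gap_policy == "drop":
        records = [_degap_record(r) for r in records]

    per_group: dict[str, dict] = {}
    for rec in records:
        if rec.id not in taxa:
            continue
        group = taxa.group_of(rec.id, group_key)
        role = taxa[rec.id].role
        entry = per_group.setdefault(
            group, {"role": role, "fwd": [], "rev": [], "clamp": 0}
        )
        clamp_hit = False
        for key, primer in (("fwd", fwd), ("rev", rev)):
            site = best_site(primer, rec, max_mm=max_mm_scan)
            if site is None:
                entry[key].append(max_mm_scan + 1)
                clamp_hit = True
            else:
                entry[key].append(site.mismatch_count)
                if any(
                    p <= clamp_window for p in site.mismatch_positions_from_3prime
                ):
                    clamp_hit = True
        if clamp_hit:
            entry["clamp"] += 1

    rows = [
        ProfileRow(
            group=g,
            role=e["role"],
            n_sequences=len(e["fwd"]),
            fwd_min=min(e["fwd"]),
            fwd_median=median(e["fwd"]),
            fwd_max=max(e["fwd"]),
            rev_min=min(e["rev"]),
            rev_median=median(e["rev"]),
            rev_max=max(e["rev"]),
            n_clamp_mismatch=e["clamp"],
        )
        for g, e in per_group.items()
    ]
    rows.sort(key=lambda r: (_ROLE_ORDER.get(r.role, 9), r.group))
    return MismatchProfile(rows=tuple(rows), clamp_window=clamp_window)


@dataclass(frozen=True)
class SpecificityRow:
    template_id: str
    group: str
    role: str
    amplifies: bool
    product_lengths: tuple[int, ...]
    adaptor_linked_lengths: tuple[int, ...]
    copy_number: int = 1             # report column only; the in-silico
                                     # outcome is concentration-independent


@dataclass(frozen=True)
class SpecificityTable:
    rows: tuple[SpecificityRow, ...]

    def amplified_ids(self) -> list[str]:
        return [r.template_id for r in self.rows if r.amplifies]

    def to_tsv(self) -> str:
        buf = io.StringIO()
        buf.write(
            "template\tgroup\trole\tcopy_number\tamplify\tlength_bp\t"
            "adaptor_linked_length_bp\n"
        )
        for r in self.rows:
            lengths = ",".join(map(str, r.product_lengths)) or "-"
            linked = ",".join(map(str, r.adaptor_linked_lengths)) or "-"
            buf.write(
                f"{r.template_id}\t{r.group}\t{r.role}\t{r.copy_number}\t"
                f"{'yes' if r.amplifies else 'no'}\t{lengths}\t{linked}\n"
            )
        return buf.getvalue()

    def gel_report(self) -> str:
        """Human-readable gel-style block: one lane per template."""
        lines = ["lane  band      template"]
        for r in self.rows:
            band = "====" if r.amplifies else "    "
            size = f"~{r.product_lengths[0]}bp" if r.amplifies else "  -  "
            lines.append(f"{band:>5} {size:>8}  {r.template_id} ({r.group}, {r.role})")
        return "\n".join(lines) + "\n"


def specificity_table(
    fwd: Primer,
    rev: Primer,
    panel: list[SequenceRecord],
    taxa: TaxonMap,
    rules: AmplificationRules | None = None,
    *,
    group_key: str = "class",
    copy_numbers: dict[str, int] | None = None,
) -> SpecificityTable:
    """Amplify / no-amplify call per template — the computational analogue of
    running the primer set across a cloned template panel on a gel."""
    rules = rules or AmplificationRules()
    copy_numbers = copy_numbers or {}
    rows = []
    for rec in panel:
        preds = predict_amplicons(fwd, rev, rec, rules)
        group = taxa.group_of(rec.id, group_key) if rec.id in taxa else "?"
        role = taxa[rec.id].role if rec.id in taxa else "?"
        rows.append(
            SpecificityRow(
                template_id=rec.id,
                group=group,
                role=role,
                amplifies=bool(preds),
                product_lengths=tuple(p.length_bp for p in preds),
                adaptor_linked_lengths=tuple(
                    p.adaptor_linked_length_bp for p in preds
                ),
                copy_number=copy_numbers.get(rec.id, 1),
            )
        )
    return SpecificityTable(rows=tuple(rows))
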