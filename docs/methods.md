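# Methods

This note records the models, conventions and deliberate design choices
behind `cladeprimer`, in the spirit of a package vignette: what is computed,
under which assumptions, and what the synthetic panels do and do not show
about real data.

## Primer representation and arithmetic

A primer is a core over the 15 IUPAC nucleotide codes, a set of 1-based LNA
positions counted from the 5′ end, and an optional plain-ACGT adaptor.
Positions are reported in both conventions (from 5′ and from 3′; the 3′
form is `length − pos5 + 1`) because both appear in primer literature and
mixing them silently is a classic source of off-by-one errors. LNA residues
are modeled structurally plus a configurable additive Tm increment
(default +4.0 °C per residue); published increments for internal LNA span
roughly +2 to +8 °C depending on context, and a full LNA nearest-neighbor
parameter set is deliberately out of scope. The base Tm is nearest-neighbor
(unified DNA parameters via Biopython) at 50 mM Na⁺ and 250 nM oligo,
summarized as min/mean/max over the degenerate expansions.

Comparison against a reference primer uses an exhaustive ungapped offset
scan (both cores ≤ ~40 nt, so brute force is exact), maximizing
IUPAC-compatible aligned positions; ties prefer fewer substitutions, longer
overlap, then the smallest offset. Positions whose base sets intersect
(M vs A) are compatible, not substitutions — a degenerate base is a claim
about the template population, not a mismatch. Primers whose best anchor has
fewer than 8 compatible bases are declared incomparable rather than given a
meaningless offset.

One discrepancy in the shipped definitions is recorded rather than
resolved: the narrative description of the reverse primer's locked base
("sixth adenine from the 5′ end") conflicts with the tabulated bold
position 6, which is the third adenine. The shipped definition follows the
table (position 6, 1-based from 5′).

## In-silico PCR

A position mismatches iff the IUPAC base sets are disjoint; a gap in the
site mismatches everything. Mismatch positions are reported 1-based from
the primer's 3′ end because 3′-proximal mismatches are what suppress
polymerase extension. Reverse primers are scanned as their
reverse-complemented core on the plus strand, so their 3′ end corresponds
to the *start* of the plus-strand footprint; all coordinates are 1-based
inclusive plus-strand.

Wet-lab amplification has no published mismatch threshold, so the decision
rule is explicit configuration with stringent conventional defaults: at
most 1 mismatch per primer, 0 mismatches in the 4-base 3′ clamp, product
length 80–2000 bp. Whether a single clamp-internal mismatch truly abolishes
amplification in vitro varies by polymerase and annealing conditions; the
default treats it as blocking and `AmplificationRules` exposes every knob.
Template copy number is carried as a report column only: the in-silico
outcome is concentration-independent, which is precisely the claim being
made when a plant template stays dark even at 100× excess — a documented
modeling limitation, not an oversight. In aligned panels, gap columns are
dropped per sequence before scanning (configurable to count gaps as
mismatches instead).

## Design scan

The window search is the algorithmic form of a manual alignment read: per
column, the minimal IUPAC code covering all observed target-row bases (gaps
ignored below 50 % of rows, gap-majority columns unusable); windows are
rejected when consensus degeneracy exceeds the cap (default 4 — shipped
primers have degeneracy ≤ 2). Each window scores (a) target coverage, the
fraction of target rows within 1 mismatch of the consensus; (b) per
excluded group, the minimum mismatch count of any member — the weakest link
an escaping template would exploit; (c) a 3′-weighted mismatch sum
(positions 1–4 from 3′ weigh 3, 5–8 weigh 2, rest 1). Pairs within product
bounds (default 200–350 bp) rank lexicographically by worst-case exclusion
margin, coverage, weighted discrimination, with a leftmost-window
tie-break, making the output deterministic. The ranking itself is this
package's formalization; the weight schedule encodes the 3′-emphasis that
motivates clamp-proximal LNA placement and is configurable.

LNA proposal: a position qualifies when **all** plant rows mismatch the
consensus there (locking a base that some plants match would sharpen
binding to those plants — the opposite of the intent); up to 2 positions
per primer, highest 3′ weight first.

Two scoring paths exist deliberately: a direct per-window evaluator
(reference semantics) and a prefix-sum scan that makes the exhaustive pair
search O(1) per window after an O(rows × columns) precomputation. The test
suite asserts their agreement on the scan's own output.

## Distances, trees, classification

TN93 distances use the closed-form estimator from the observed purine
transitions, pyrimidine transitions and transversions with base frequencies
pooled over the pair; sites with a gap or ambiguity in either sequence are
excluded (pairwise deletion — amplicons are short, complete deletion is
available for matrix construction). Non-positive logarithm arguments are
flagged as infinite (saturation) rather than clipped; degenerate
compositions (no purines or no pyrimidines among usable sites) skip the
vanishing terms. The implementation is checked against an independently
coded direct transcription of the formula to 1e−12 and against the
Jukes–Cantor closed form on a symmetric-composition construction.

Neighbor joining is the canonical Q-criterion algorithm with a
deterministic lowest-index tie-break; negative branch-length estimates are
clamped to zero (standard practice) with a log note. On additive matrices
the tree's path-length matrix reproduces the input to 1e−9, which is the
algorithm's defining correctness property and the main oracle used in
testing. Trees render to canonical Newick (children sorted by smallest
descendant leaf), so identical analyses are byte-identical and leaf order
is irrelevant.

Bootstrap resamples alignment columns with replacement; support for each
internal bipartition of the full-data tree is the percentage of replicate
NJ trees containing it, from a single seeded generator per run. All tree
outputs are labeled NJ (TN93): the nearest-clade classification use-case
does not require a likelihood tree search, and a distance method is fully
specifiable and testable at desk scale — this substitution is intentional
and global.

Query assignment places each clone on the reference coordinates by the best
ungapped offset (≥ 50 % identity required), then assigns the class of the
TN93-nearest reference. The margin — distance gap to the nearest
*other-class* reference — is the natural confidence score for
closely-related-clade typing; exact ties raise an ambiguity flag instead of
an arbitrary pick.

## Synthetic panels: what they emulate, and what they don't

The generators exist because no accession set accompanies the primer-design
narrative they operationalize; they reproduce its *structure*: a shared
~1700 nt backbone (18S-scale) with substitution-only divergence between
groups (default 5 %) and within groups (default 1 %), and primer windows
planted with exact per-clade mismatch recipes — targets 0, plants 2–3 per
window, Mucoromycetes 2–3 forward / 2–5 reverse, Ascomycota and
Basidiomycota 1–2 placed clamp-biased so the stringent default rules
reproduce the all-or-nothing gel pattern. The default product is 260 bp
(327 bp adaptor-linked: 260 + 33 + 34, exact arithmetic behind the
"approximately 260/320 bp" a gel shows). The 13-template default panel
mirrors the published wet-lab panel's taxon structure: 5 target-class
templates among 13.

Substitution-only evolution means the reference panel is trivially its own
alignment, keeping every consumer module independent of an aligner. Real
18S data differ in ways these panels do not model: indels and alignment
uncertainty, intragenomic rRNA heterogeneity (the very reason single
vesicles yield mixed electropherograms), chimeras, and secondary-structure
covariation. Passing tests therefore demonstrate algorithmic correctness
under the stated mismatch structure, not field performance of any primer.

The design-recovery panel plants its window pair at the alignment edges
with edge-anchored off-target mismatches, degenerate M columns inside both
windows, and four-base "spoiler" columns flanking the interior edges. This
construction makes the planted pair the *unique* optimum of the ranking —
any extension past a window edge exceeds the degeneracy cap, any shrinkage
drops an edge-anchored mismatch and lowers the exclusion margin — so
recovery is a sharp test of the scan, not a statistical accident.

Vesicle-clone simulation draws 5–84 clones from class-weighted templates,
extracts the planted amplicon region and applies uniform per-base error
(default 0.5 %, Sanger-plus-PCR scale). At the default divergences
(≥ ~5 % between classes, ≤ ~1.5 % within, errors ≤ 0.5 %) nearest-reference
assignment recovers the generating class essentially always; that headroom
is intended, since the claim under test is correctness of the machinery.

All generators are bit-reproducible under a fixed seed, and every panel
ships a truth table that tests re-derive by directly recounting window
mismatches on the emitted sequences.

## Problem sizes and numerical conventions

The shipped analyses are sized for a desk run: 13-template panels of
1700 nt, design panels of 10 × 260 nt scanned exhaustively
(~4000 windows/orientation), 100 design panels for the recovery rate,
84 clones for classification accuracy, 100 bootstrap replicates (the
conventional reporting standard). Tolerances: TN93 vs oracle 1e−12, NJ
additivity 1e−9, exact integer equality for all mismatch counting and
primer arithmetic. Tie-breaks everywhere are deterministic (lowest index /
leftmost window / lexicographic), so every pipeline is reproducible from a
single integer seed.
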