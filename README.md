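# cladeprimer

Design and in-silico validation of clade-discriminative 18S rRNA primers,
with distance-based classification of the amplicons they produce.

## The problem

Arbuscular mycorrhizal fungi of the subphyla Glomeromycotina (G-AMF) and
Mucoromycotina (M-AMF) co-colonize plant roots, but profiling them by PCR is
hard: universal fungal primers co-amplify plant rDNA and non-mycorrhizal
fungi, drowning out the trace M-AMF signal. What is needed is a primer pair
that binds the 18S rRNA gene of most Mucoromycota — Glomeromycetes,
Mortierellomycetes, Endogonomycetes, Umbelopsidomycetes — while rejecting
Mucoromycetes (non-mycorrhizal molds) and plants, and yields a short V4
amplicon suitable for both Sanger typing of single intracellular structures
(vesicles) and Illumina MiSeq metabarcoding.

`cladeprimer` is the desk half of that workflow, for primer designers and
molecular ecologists:

- **Primer model** — oligonucleotides with IUPAC mixed bases (e.g. M = A/C),
  locked-nucleic-acid (LNA) annotations in a `+`-markup dialect
  (`GTTAAAAAGCTCGTAGTTGAA+TTT` locks the 22nd base), plain length-bearing
  sequencing adaptors, nearest-neighbor Tm with a per-LNA increment, and
  structural comparison against reference primers by exhaustive anchored
  overlap.
- **Specificity engine** — in-silico PCR. A primer binds a template window
  when their IUPAC base sets intersect position-wise; a template amplifies
  when both primers pass a mismatch cap (default ≤ 1) and carry no mismatch
  in the 3′-terminal clamp (default 4 bases), with the product inside length
  bounds. Outputs per-taxon mismatch profiles and an amplify/no-amplify
  "gel" table.
- **Primer design** — exhaustive scan of a labeled alignment for window
  pairs whose target-row consensus is nearly invariant while every excluded
  group mismatches it, ranked by (worst-case exclusion margin, target
  coverage, 3′-weighted discrimination); proposes LNA exactly where all
  plant rows mismatch the consensus.
- **Phylogenetic classification** — Tamura–Nei (TN93) pairwise distances,
  canonical neighbor-joining, column-bootstrap supports, and
  nearest-reference class assignment with an ambiguity margin.
- **Synthetic fixtures** — reproducible 18S-like panels with planted primer
  windows and per-clade mismatch structure, so the whole toolkit is testable
  without any sequence download.

The TN93 distance between two aligned sequences uses the standard estimator
from the observed purine-transition, pyrimidine-transition and transversion
proportions $P_1, P_2, Q$ and pooled base frequencies:

$$d = -\frac{2\pi_A\pi_G}{\pi_R}\ln w_1 - \frac{2\pi_T\pi_C}{\pi_Y}\ln w_2
      - 2\Big(\pi_R\pi_Y - \frac{\pi_A\pi_G\pi_Y}{\pi_R} - \frac{\pi_T\pi_C\pi_R}{\pi_Y}\Big)\ln w_3$$

with $w_1 = 1 - \frac{\pi_R P_1}{2\pi_A\pi_G} - \frac{Q}{2\pi_R}$, analogously
$w_2$, and $w_3 = 1 - \frac{Q}{2\pi_R\pi_Y}$; a non-positive logarithm
argument is flagged as saturation.

## Worked example

Generate a 13-template panel shaped after a typical specificity experiment
(five target-class templates, two Mucoromycetes, two Ascomycota, two
Basidiomycota, two plants) and run in-silico PCR with the shipped
clade-specific pair:

```bash
cladeprimer simulate templates --seed 3 --out fixtures/
cladeprimer ispcr --fwd BM0639-5LNA --rev BM0853-3LNA \
    --templates fixtures/templates.fasta --taxa fixtures/taxa.tsv --out run/
```

which prints the gel-style report:

```
lane  band      template
 ====   ~260bp  Glomeromycetes_1 (Glomeromycetes, target)
 ====   ~260bp  Mortierellomycetes_1 (Mortierellomycetes, target)
 ====   ~260bp  Endogonomycetes_1 (Endogonomycetes, target)
 ====   ~260bp  Endogonomycetes_2 (Endogonomycetes, target)
 ====   ~260bp  Umbelopsidomycetes_1 (Umbelopsidomycetes, target)
           -    Mucoromycetes_1 (Mucoromycetes, excluded)
           -    Mucoromycetes_2 (Mucoromycetes, excluded)
           -    Saccharomycetes_1 (Saccharomycetes, excluded)
           -    Sordariomycetes_1 (Sordariomycetes, excluded)
           -    Agaricomycetes_1 (Agaricomycetes, excluded)
           -    Ustilaginomycetes_1 (Ustilaginomycetes, excluded)
           -    Magnoliopsida_1 (Magnoliopsida, excluded)
           -    Liliopsida_1 (Liliopsida, excluded)
```

Exactly the five target-class templates amplify: a 260 bp core product
(327 bp once the 33 + 34 nt sequencing adaptors are counted). The plants
carry 2–3 mismatches per primer and stay dark at any template copy number;
the other non-targets are blocked by the mismatch cap or the 3′ clamp.
`run/ispcr.tsv` holds the same calls machine-readably.

Classify simulated single-vesicle clones against their reference panel:

```bash
cladeprimer simulate clones --seed 4 --out cl/
cladeprimer classify --queries cl/clones.fasta --refs cl/refs.fasta \
    --taxa cl/taxa.tsv --bootstrap 100 --seed 1 --out cls/
```

```
query	class	nearest_ref	distance	margin	ambiguous
clone_1	Mortierellomycetes	Mortierellomycetes_3	0.003876	0.103498	false
clone_2	Glomeromycetes	Glomeromycetes_3	0.015612	0.087378	false
clone_3	Endogonomycetes	Endogonomycetes_2	0.003857	0.117083	false
...
```

Each clone is assigned the class of its TN93-nearest reference; `margin` is
the distance gap to the closest other-class reference (a zero margin flags
an ambiguous call). `cls/reference_tree.nwk` carries the NJ (TN93) reference
tree with bootstrap supports from 100 column resamples.

Other subcommands: `cladeprimer design` (window search on a labeled
alignment, reporting primer specs in `+`-markup), `cladeprimer evaluate`
(per-taxon mismatch profile), `cladeprimer simulate panel`.

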