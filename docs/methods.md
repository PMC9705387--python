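# Methods

## Problem setting

Modern commercial sugarcane is an auto-allopolyploid hybrid of
*Saccharum officinarum* and *S. spontaneum*.  The two progenitor genomes
are extremely similar — on the order of 94% nucleotide identity over more
than 90% of their length — which is below the raw error rate of
consensus-corrected long reads.  When an assembly of such a hybrid is
aligned back to both progenitor references, contigs can be assigned a
subgenome ancestry, and contigs whose ancestry *switches* along their
length ("recombinant" or chimeric contigs) can be counted.  An excess of
such contigs, relative to what cytogenetics says about subgenome isolation,
is a diagnostic of assembly artifacts rather than biology.  `subpaint`
implements that diagnostic as a reusable pipeline, together with a seeded
simulator that generates hybrid assemblies with known ancestry so every
stage can be validated against exact truth.

## Ancestry calling

For each contig we take alignments against progenitor A and progenitor B
(show-coords tables, PAF, or SAM; all normalized to 0-based half-open
coordinates on entry).  Per reference, overlapping query ranges are merged
to disjoint unions — the "reduce to a single range" step that all coverage
accounting rests on.

Because the progenitors are so similar, most contig bases align to *both*
references; raw per-reference coverage is therefore nearly uninformative on
its own.  Bases are credited **competitively**: the contig is cut at all
alignment boundaries, and each piece covered by both references is credited
to the side whose best local alignment identity is higher, unless the two
identities are within `identity_margin_pct` (default 1.0 percentage
points), in which case both sides are credited.  A piece covered by only
one reference is credited to that side.  This is the same resolution rule
as competitive read mapping: ties mean "genuinely ambiguous", not "both".

Writing bp_A and bp_B for the credited totals and L for the contig length,
the category is decided in fixed precedence order:

1. **unaligned** — max(bp_A, bp_B)/L < `min_aligned_frac` (default 0.10);
2. **recombinant** — the alternating-run test below fires;
3. **equal** — |bp_A − bp_B| / (bp_A + bp_B) ≤ τ (`equal_tolerance`,
   default 0.10), the "mapped almost equally to both ancestors" case;
4. otherwise **A_dominant** or **B_dominant**.

### Recombinant detection

Ancestry switching is detected on ancestor-*exclusive* credit: bases
credited to exactly one side.  The contig is tiled into `window_bp`
(default 1 kb) windows; each window is labelled A or B by majority of
exclusive credited bp (ties and empty windows are unlabelled and do not
break runs).  Maximal same-label runs qualify when they span at least

    max(recomb_min_segment_bp, recomb_min_segment_frac × aligned bp)

with defaults 10 kb and 0.05.  The contig is recombinant iff the
qualifying runs include both ancestries; breakpoints are placed at the
midpoint between consecutive qualifying runs of different ancestry, so the
localization error is bounded by about half a window plus the gap between
runs.  The bp floor is the binding threshold at typical contig sizes; the
fractional term only suppresses alternation calls built from a sliver of a
very sparsely aligned contig.  A fractional default much larger than this
would veto genuine minority segments (a 20%-of-contig requirement rejects
roughly a third of uniformly placed single-breakpoint chimeras outright),
which is why 0.05 is the default rather than a "half and half" reading.

### Two-pass design

Tallies and categories come from the first (permissive) alignment pass.  A
second pass at different stringency is used only to re-examine "equal"
contigs: their tallies are recomputed on the second-pass alignments and the
contig is reassigned to the now-dominant side when the tolerance test
fails.  The passes are deliberately named pass1/pass2 rather than
lenient/strict — which alignment settings are effectively stricter depends
on the aligner and scoring, and nothing downstream depends on the label.
Disambiguation can only shrink the equal class; contigs without second-pass
data stay equal with a warning.

## Depth partition

Collapsed repeats and collapsed alleles inflate mapped read depth.  The
genome-wide reference point is the **length-weighted median** of per-contig
depths (the depth at which half the assembly bp lies in contigs no
deeper) — bp weighting, rather than a plain median over contigs, because
the output is a bp partition of the assembly.  A contig is multi-copy iff
its depth strictly exceeds `depth_multi_threshold` × median (default 1.5);
ties are single-copy.

## Whole-genome comparison and unplaced concordance

`compare_genomes` reports covered fractions on both sides (merged ranges
over total bp, with unaligned sequences kept in the denominator so the
figure is genome-wide) and average nucleotide identity both
alignment-column-weighted and as a plain mean over alignments.  The
weighted form is the headline statistic — an unweighted mean lets short
spurious hits dominate — but both are reported because published "average
identity" figures rarely say which was used.

`unplaced_concordance` measures (a) the fraction of unplaced-contig bp that
aligns onto the pseudochromosomes and (b) among A/B-dominant unplaced
contigs over A/B-painted target bases, the fraction of aligned bp whose
ancestry agrees with the painting.  Equal, recombinant and unaligned
categories are excluded from both sides of the concordance term: they have
no single ancestry to agree or disagree with.

## Paintings and repeat summaries

Paintings color each placed contig block by its category with a fixed
palette (A teal `0,128,128`, B green `34,139,34`, equal pink
`255,105,180`, recombinant purple `128,0,128`, unaligned grey); the
two-track variant adds unplaced contigs at their merged alignment
footprints.  Contigs below `min_display_bp` (default 100 kb) are dropped
from display only, never from totals.

Repeat summaries keep two views deliberately: per-class masked bp (hits of
one class merged per target, so a base hit twice by the same class counts
once) and the cross-class union, bridged by closing gaps strictly shorter
than 10 bp before counting regions larger than 20 kb.  Per-class sums can
legitimately exceed the union because classes overlap; the grand-total row
is always recomputed as the sum of the per-class rows rather than taken on
trust.

## The simulator

`synthdata` emulates the statistical structure the pipeline is meant to
detect, not sugarcane biology:

- **Progenitors.**  Genome B is derived from A by iid substitutions at rate
  `divergence` (default 0.057, i.e. ~94.3% identity), uniform over the
  three alternative bases; short 1–3 bp indels are opt-in
  (`indel_rate`, default 0) and recorded as offset maps so truth
  coordinates stay exact.  Defaults: 1 Mb over 5 chromosomes — large
  enough that binomial bounds on realized divergence are tight (SD of the
  realized identity ≈ 0.02 pct points at 1 Mb), small enough for
  seconds-scale tests.
- **Hybrid contigs.**  200 contigs, uniform 120–180 kb, copied from a
  uniform window of one progenitor; with probability `chimera_fraction`
  (0.20) the contig is stitched across progenitors at 1–3 uniform
  breakpoints, re-drawn until every segment exceeds 5 kb.  Pure contigs
  come from A with probability 0.70, mirroring the 2:1 chromosome dosage
  of the initial interspecific cross.  The contig-length default keeps
  planted chimeric segments comfortably resolvable against the detector's
  10 kb run floor; segments between 5 and 10 kb are planted but below the
  detector's design minimum, which is why breakpoint error is reported as
  the localization error of *reported* breakpoints while wholly-missed
  segments are charged to sensitivity.
- **Truth alignments.**  Each planted segment yields a 100%-identity record
  to its source progenitor and a record to the other progenitor at the
  exactly-computed cross identity.  This idealizes an aligner: coverage is
  complete on both references and only identity separates them — the
  hardest regime for coverage-based calling and precisely the regime the
  competitive crediting is built for.  What it does *not* emulate:
  alignment fragmentation, repeat-induced multi-mapping, indel-driven
  coordinate drift, or identity noise along a contig.  Passing recovery
  tests therefore demonstrate the classifier logic, not aligner robustness.
- **Depth.**  Per-contig depth = 13 × planted copy number (+ optional
  seeded integer noise); ~10% of contigs are planted at copy number 2–3.
  With zero noise the depth partition must recover planted collapsed bp
  exactly, and does.
- **Placements.**  A random ~70% of contigs are laid on pseudochromosomes
  in source order with 100 bp U-gaps; the remainder form the unplaced set,
  with truth alignments of unplaced contigs onto the scaffolds derived
  from source-window overlaps.

Identical parameters and seed give byte-identical outputs; all sub-streams
(assembly, depth, AGP) derive distinct seeds from the master seed.

## The consensus-correction model

The chimerization mechanism — short reads from the wrong subgenome
recruited to correct a long read when subgenome divergence d is below the
read error rate e — is modelled per diagnostic site (a position where the
subgenomes differ).  A long read from subgenome A carries the A allele
unless a read error (probability e, default 0.12) flipped it.  `c_a` and
`c_b` short reads (error e/10) are recruited when their identity to the
long read over a w-bp window centred on the site is at least 1 − e − m
(margin m, default 0.05; w default 100).  The corrected base is the modal
base among recruited reads; ties or an empty recruit set keep the long
read's own base.  The reported rate is the fraction of sites corrected to
the B allele.

Default coverages are equal (c_a = c_b = 6, ~13 total, matching the
simulated median depth): in a high-ploidy hybrid, short reads from every
homoeologous copy of a conserved window map to the long read at similar
rates.  The model is the verbal mechanism made quantitative — majority
vote over identity-recruited reads — not a reimplementation of any
assembler's correction stage.  Its testable properties: the rate is 0 when
e = m = 0 (a B read always mismatches the diagnostic site), 0 at d = 0 by
convention (no diagnostic sites exist), and monotone non-increasing in d
(more divergence means B reads fail recruitment).  A Monte-Carlo mode
(vectorized, seeded) is checked against an exact mode that enumerates
long-read error counts, divergent-position counts, their overlap and the
site bases, convolves per-class mismatch binomials, and runs a vote-count
DP over reads; the exact mode is intended for w ≤ ~20 and small coverage.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open everywhere internally; 1-based
  inclusive formats (coords, RepeatMasker, AGP) convert at the boundary.
- Merging treats touching intervals as one; bridging closes gaps strictly
  shorter than the threshold (a gap of exactly 10 bp survives), and "large
  region" means strictly larger than 20 kb.
- SAM identity is 100·(columns − NM)/columns with columns = M/=/X + I + D,
  falling back to =/X counting; records with neither fail loudly.  Reverse
  strand query ranges are flipped onto the original contig using the full
  read length including hard clips.  A score filter (AS tag) with a
  missing tag is an error, not a silent pass.
- Empty inputs: weighted identity of no alignments is an error (not 0);
  concordance with an empty denominator is reported as absent (None);
  depth partition of no contigs is an error.
- Chromosome-normalized recombination ratio is (n₁/c₁)/(n₂/c₂); it is
  scale-invariant and maps argument swap to the reciprocal.

## Known limitations

- Calls rest on per-alignment identity; there is no base-level
  realignment, so two references tied within the identity margin are
  genuinely indistinguishable to the caller (by design — that is the
  "equal" class).
- The recombinant detector cannot see ancestry segments below its run
  floor; sensitivity to chimeras whose minority segment is under 10 kb is
  deliberately limited.
- The simulator's truth alignments have no coordinate noise, so recovery
  numbers are upper bounds on what the same thresholds achieve on real
  aligner output.
- Exact reproduction of published recombinant-contig *counts* is not
  promised: they depend on aligner settings and undocumented minimum
  segment conventions in the original analysis; the pipeline exposes every
  threshold instead.
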