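# Methods

This note documents the models, rules and numerical choices behind `apfam`,
what the synthetic-data generator does and does not emulate, and the design
decisions taken where the procedure was genuinely open.

## Coordinates and I/O

Internal coordinates are 0-based half-open on chromosome sequences; GFF3
(1-based inclusive) is converted at the parse/serialize boundary. Assemblies
are uppercased and restricted to {A,C,G,T,N}; other ambiguity codes are
rejected by default (or mapped to N with `ambiguous="map-n"`) because the
promoter scanner's semantics require an exact subject alphabet. One gene
model is built per gene from its *primary transcript*: the mRNA whose ID
ends `.1` (the Phytozome convention), else the mRNA with the longest CDS;
the rule used is recorded per gene, since annotation sources rarely state
which isoform a published survey used.

## Family identification

A candidate has a **perfect ORF** when its CDS starts with ATG, ends with a
stop codon, contains no internal stop, and has length divisible by three.
The catalytic scan reports every `D[TS]G` occurrence (X never matches); the
**complete domain** call requires a pair of catalytic Asp positions spaced
within [`min_gap`, `max_gap`] residues, defaults 100–350. The generous
upper bound deliberately accommodates the PSI insert of typical APs, which
sits between the catalytic motifs and lengthens the spacing. Profile-HMM
domain scoring (SMART/CDD-style) is out of scope; the spacing rule is the
tunable stand-in.

Categories, applied only to domain-complete members:

- **A (typical)** — PSI heuristic: ≥ 6 cysteines within a 120-residue
  window lying strictly between the two chosen Asp positions. Six is the
  canonical cysteine count of the saposin-like fold; the window reflects the
  ~100-residue insert plus slack. When the inter-Asp region is shorter than
  120 residues the whole region is the window (a longer window cannot "lie
  strictly between").
- **B (nucellin-like)** — both QCDYE and GCGYDQ present with ≤ 1
  substitution each ("highly conserved", not invariant).
- **C (atypical)** — neither feature. Precedence is A > B; a protein
  matching both is reported as A with a conflict flag.

Molecular weights are ExPASy-style average residue masses plus one water
(18.0153 Da), reported to 2 decimals. Localization labels from external
predictors are aggregated by strict majority; ties and pluralities short of
a majority yield `ambiguous`.

## Phylogeny

Distances are Poisson-corrected protein distances (−ln(1−p)) with pairwise
deletion of gap columns; p-distance is selectable. This is the common
default for distance-based protein trees where the original tool settings
are unrecorded. NJ is the standard Saitou–Nei agglomeration; Q-matrix ties
break deterministically toward the lowest index pair in node-creation
order. Negative branch-length estimates are clamped to zero and flagged.
On additive matrices the tree's path-length metric reproduces the input to
< 1e−9 (property-tested). Bootstrap support is the percentage of
column-resampled replicate trees containing each internal bipartition of
the full-data tree; replicates whose resampled distances are undefined
(saturation) are skipped and count against support.

The built-in aligner is a center-star progressive method (3-mer profile
distances choose the center; every sequence is globally aligned to it with
BLOSUM62, gap open −10, extend −0.5; gaps merge by "once a gap, always a
gap"). It is deliberately simple and flagged approximate — for real data an
externally computed alignment (MAFFT, Clustal) should be supplied as
aligned FASTA. Pairwise percent identity is identical aligned pairs over
alignment columns, rounded to the nearest integer.

## Duplications, Ka/Ks and dating

Tandem duplication: family genes whose nearest gene-boundary gap is
≤ 50 000 bp on the same chromosome, clustered by single linkage; clusters of
size ≥ 2 are reported. The distance is between gene boundaries (not
midpoints), and family membership itself is the "closely related" criterion
since the input is already the identified family. The boundary case (gap
exactly 50 kb) is included.

Segmental duplication: a pair is emitted when the two genes overlap (≥ 1 bp)
the two sides of the same duplicated block; the block table is an input
(PGDD-style), not derived here. All block-supported pairs are emitted; a
published pair list can be used to subset when reproducing a specific
survey.

Ka/Ks is Nei–Gojobori (1986) with Jukes–Cantor correction — the classical
estimator for family surveys whose source database did not name one.
Per-codon synonymous-site fractions are computed over single-nucleotide
neighbors with changes to stop codons excluded from numerator and
denominator; sites are averaged over the two sequences, so S + N = 3 ×
aligned codons exactly. Multi-nucleotide codon differences average the
synonymous/nonsynonymous step counts over all minimal mutational pathways
whose intermediates avoid stops; in the degenerate case where every pathway
passes through a stop, the average falls back to all minimal pathways
(unreachable on stop-free data). ps or pn ≥ 3/4 flags saturation and leaves
Ks/Ka undefined rather than raising. The codon alignment is induced from a
protein alignment (supplied or computed), trailing stop codons stripped,
gap columns dropped, and codon pairs containing N dropped with a count.

Dating: `T = Ks / (2λ)` with λ = 9.1 × 10⁻⁹ synonymous
substitutions/site/year (the *Populus* clock rate); Ks = 0.182 dates to
exactly 10 Mya. Selection classes: ratio < 1 purifying, = 1 neutral, > 1
positive, undefined when Ks = 0 or saturated.

## Promoter cis-element scan

The promoter is the `length_bp` (default 3000) window upstream of the
transcription start — the 5′-most transcript coordinate, i.e. upstream of
the 5′-UTR — reported 5′→3′ on the coding strand and truncated (with a
flag) at chromosome edges. Genes lacking an annotated 5′-UTR anchor at the
CDS start, flagged.

The built-in catalog holds the ten SCW elements as IUPAC consensi: SNBE
(WNNYBTNNNNNNNAMGNHW), TERE (CTTNAAAGCNA), M46RE (RKTWGGTR), ACI (ACCTACC),
ACII (ACCAACC), ACIII (ACCTAAC), SMRE1 (ACCAAAT), SMRE2 (ACCAACT), SMRE3
(ACCAAAC), SMRE5 (ACCTAAT). Matching is exact set membership per position
(implemented as vectorized bitmask tests); an N in the subject never
matches any code, including consensus N, so masked sequence cannot produce
hits. Both strands are scanned by default — several of these elements act
orientation-independently and the original surveys rarely state strand
handling — with minus-strand hits reported at their 5′-most promoter
coordinate; plus-only mode is available to probe the sensitivity of
presence calls. Every occurrence at every offset is reported (overlaps
included); presence/absence is derived downstream, so overlap handling does
not affect presence calls.

## Glycosylation

Sequons are the canonical acceptor pattern N-X-[S/T] with X ≠ P,
overlapping occurrences all reported. This upper-bounds neural-network
predictions (NetNGlyc-style), which score context beyond the pattern; the
published per-protein positive counts are therefore not comparison targets.
The category-B "conserved site between the invariant Tyr75 and GCGYDQ" is
operationalized per sequence as any sequon within 60 residues upstream of
the GCGYDQ match (≤ 1 mismatch); pepsin-reference numbering would require
an external reference alignment, so the window is an explicit, configurable
approximation.

## Expression

Matrices are genes × tissues of non-negative intensities (tissue codes ML,
YL, RT, FC, MC, XY). The xylem rule selects genes with XY value strictly
above the threshold (default 1000, strict because the rule is printed as
"> 1000") and then closes the set over duplication-pair partnership
("corresponding replication genes"); the closure is idempotent. Heat-map
clustering transforms log2(x+1) — the +1 offset handles zeros — and uses
average linkage on Euclidean distances, the common default where the
original tool's settings are unrecorded. 2^−ΔCt is the comparative-Ct
relative expression. The significance test is a two-sided two-sample
t-test, pooled variance by default, with stars p < 0.05 → `*`,
p < 0.01 → `**`; two zero-variance groups with equal means give p = 1.

## Synthetic data: the stated world

Defaults mirror the characterized family: 67 genes in a 7/6/54 A/B/C mix on
19 chromosomes; tandem clusters of sizes 3, 2 and 6; ten segmental pairs
with target synonymous counts 10–40 and nonsynonymous counts 1–5; one to
three planted cis-element instances per 3-kb promoter; 12 xylem-specific
expression archetypes (XY = 1500, elsewhere 50) against non-specific
profiles drawn in 100–800 with Gaussian noise (sd 50); a quarter of genes
lack a 5′-UTR; exon counts are drawn uniformly in 1–12. Chromosomes are
1.2 Mb so worst-case layouts (a six-gene cluster plus singletons at
non-tandem spacing) always fit; infeasible configurations raise.

Two constructions make recovery exact by design rather than by tolerance:

- Protein backgrounds are drawn from the 18-letter alphabet without Cys and
  Asp. Without Asp, no accidental `D[TS]G` can arise, so the planted
  catalytic motifs are the only ones; without Cys, no accidental PSI window
  can fire; and because QCDYE/GCGYDQ each contain both a C and a D, any
  background 5/6-mer is ≥ 2 mismatches away, so fuzzy nucellin matches
  cannot arise either. Category recovery is therefore exact, which is what
  the recovery tests assert.
- Tandem clusters are recent copies of a founder gene and segmental
  partners are evolved copies (8–25 synonymous, 1–4 nonsynonymous changes
  for tandem; configured counts for segmental), applied at distinct codons
  with nonsynonymous changes kept away from planted features (start codon,
  Cys/Asp motif regions, sequons) and restricted to background amino acids.
  Realized counts equal requested counts, giving known-truth input for the
  Ka/Ks estimator; inter-gene gaps are drawn 20–45 kb within clusters and
  60–120 kb otherwise, so the 50-kb rule separates them deterministically.

Not emulated: indels and rate heterogeneity in coding evolution, non-uniform
base composition (GC is uniform 50% by default; degenerate-element false
positive rates depend on it), transposable elements, alternative isoforms,
overlapping genes, and annotation errors. A green recovery test therefore
establishes correctness of the rules on clean, planted signal — not
robustness to messy real annotations, which is what the real-data input
path and its validation against a published locus list are for.

Background promoter sequence can and does contain chance element matches
(the short AC/SMRE elements especially); the planted-truth tests require
every planted instance recovered exactly and every extra hit to be
confirmed by the independent regex-expansion oracle.

## Numerical and determinism notes

- All randomness flows through `numpy.random.Generator` seeded from a
  single config/CLI seed; same seed ⇒ byte-identical outputs.
- NJ tie-break: first minimum in row-major upper-triangle order, i.e. the
  lowest index pair; bootstrap replicates re-seed from one generator.
- NG86 saturation uses the exact 3/4 boundary; comparisons across
  implementations can flip the flag within ~1e−15 of the boundary (the
  tests account for this at the boundary only).
- The Ka = 0 case returns +0.0 (not −0.0); JC correction is undefined-free
  below the boundary.
- Dates are reported in years and Mya; Mya = T / 10⁶.

## Known limitations

- The progressive aligner is approximate; category-clade correspondence on
  real data should be judged from an external MSA.
- The PSI and nucellin rules substitute for profile-HMM domain evidence;
  borderline real proteins can be mis-binned where a profile would not.
- The sequon scan upper-bounds glycosylation-site predictions.
- Blocks are trusted as given; no synteny detection is performed.
- The published genome-wide candidate counts depend on external
  BLASTP/SMART versions and are intentionally not reproduced or asserted.
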