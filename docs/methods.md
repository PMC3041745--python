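# Methods

This note records the statistical conventions, defaults and design choices
behind each analysis stage, what the synthetic-data generators do and do not
emulate, and the package's known limitations. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinate model and annotation arithmetic

Feature coordinates are 1-based inclusive on the reference (heavy, H)
strand; all internal arithmetic uses this convention and converts only at
I/O. The spacer between consecutive features is
`start(next) − end(prev) − 1`; negative values are gene overlaps. On a
circular molecule the wrap pair contributes a plain spacer, so feature
lengths plus spacers tile the genome exactly. On a *linear* contig — an
incompletely sequenced circle — the wrap record is flagged `open` and holds
head + tail of the contig; it is never reported as a plain internal spacer,
because its two pieces are the visible ends of one unsequenced region.

Long non-coding regions (LNRs) are spacers above a threshold, default
100 nt (the conventional boundary between ordinary intergenic spacers and
"large" non-coding regions in mitogenome descriptions), labelled LNR1,
LNR2, … in genome order with the open wrap region ordered at the genome
head. `validate_table` audits declared lengths and spacers against
coordinates and reports every disagreement instead of raising: published
tables carry occasional internal inconsistencies, and an audit that dies on
the first one is useless for exactly the inputs that need it. On the
packaged contig the audit flags two declared spacers ("3" where the
coordinates give 0, at the two footnote-marked rRNA boundaries) and the
prose figure of 762 nt for a region whose coordinates give 771; the
validator flags, it does not resolve.

Strand vocabulary is H/L by molecular weight; `+`/`−` are accepted on input
and normalised. Leucine/serine tRNAs are disambiguated by codon family
(trnL1 = CUN, trnL2 = UUR, trnS1 = AGN, trnS2 = UCN).

## Composition and skew

AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C), computed over unambiguous
bases; IUPAC ambiguity codes are excluded from every denominator and their
count reported. A zero denominator leaves the skew *undefined* (`None`),
never 0 — a sequence with no G or C has no GC-skew, not a neutral one.
Reverse-complementing a sequence negates both skews exactly; this is a
property test.

Per-gene profiles are computed on the sense (reading) strand — light-strand
genes are reverse-complemented first. This is what makes the anti-A skew of
protein-coding genes visible regardless of encoding strand, and it is the
convention under which codon-position partitions (1st+2nd vs 3rd) are
meaningful. For genes with truncated stop codons only complete codons enter
the positional partition.

When composition arrives as pre-tabulated percentages (published tables),
the values are divided by 100 but *not* renormalised: published rows often
sum to 100 ± 0.1 due to rounding, renormalising would silently change the
printed A+T content, and the skews are scale-free either way.

Codon usage pools counts over CDSs into counts-per-thousand; stop codons
are tallied separately and excluded from the per-thousand denominator, the
convention of standard codon-usage tables where *n* counts sense codons.
Output is rounded to 3 decimals; internal values are exact.

## Genetic code and CDS conventions

The invertebrate mitochondrial code (translation table 5) is carried as
plain data so toy codes can be injected in tests. Start codons are fixed to
the ATD set {ATA, ATT, ATG}; detecting atypical initiators is out of scope.
Stops are TAA/TAG, with 1–2 nt truncated stops (TA, T) accepted where the
reading frame ends against an abutting downstream feature — completed in
vivo by polyadenylation.

Start-codon annotation searches in-frame ATD candidates within ±9 nt of the
annotated 5′ boundary and picks the one minimising overlap with the
upstream feature, ties broken toward the longer frame. The window is a
deliberate smallness choice: real start-codon refinement weighs conserved
lengths against reference taxa, which requires external data; within a
small window the overlap-minimisation rule alone is deterministic and
reproduces typical annotations. Internal stop codons abort translation by
default (pseudogene guard).

A third-codon position is fourfold degenerate iff all four substitutions
there are synonymous under the code table; families adjacent to stop codons
are thereby excluded automatically.

## Divergence and NG86

Divergence is the uncorrected p-distance with pairwise gap/ambiguity
deletion. The choice is deliberate and documented so corrected variants can
be added: within-species distances here are ≪ 0.05 where all corrections
coincide, and between-species amino-acid distances are reported as plain
proportions.

NG86 counting: per-codon synonymous-site fractions are averaged over the
two sequences; observed differences are split by enumerating all shortest
substitution pathways between differing codons with equal weights;
Jukes–Cantor correction `d = −3/4 ln(1 − 4p/3)` is applied to both
proportions, flagged undefined when p ≥ 0.75. Mutations creating a stop
codon are counted nonsynonymous, and pathways through stops are retained
under that same policy (an explicit choice; the common alternative of
discarding such pathways changes counts only at saturated codons). Codon
columns with gaps, ambiguity codes or stop codons in either sequence are
dropped pairwise. ω = dN/dS is undefined (`None`) when dS = 0 — identical
sequences have no ω, not ω = 0. The implementation is validated against an
independent brute-force pathway-enumeration oracle in the test suite.

Group summaries: D_W is the mean nucleotide p-distance over within-group
pairs, D_B the mean between-group distance — amino acids for protein-coding
genes (nucleotide comparisons between species are saturated), nucleotides
for RNA genes. ω_W and ω_B pool NG86 site and difference counts over the
corresponding pair sets before forming proportions, which is robust to
individual pairs with zero synonymous differences. Cells that are
mathematically undefined (single-member groups, RNA genes, dS = 0) are
`None` throughout and propagate through ratio summaries.

## Gene orders

A gene arrangement is a cyclic sequence of (gene, orientation). Adjacency
retention compares unordered neighbour pairs on the circle after
restricting both orders to their shared gene set. The inversion census
anchors both orders on a shared gene (cox1 by default) with forward
orientation — reflecting one order if necessary — and counts orientation
mismatches; anchoring is what makes orientation comparison well-defined on
circles.

Common intervals are unsigned and non-trivial: gene sets of size
2 ≤ k ≤ n−1 contiguous in both orders, counted after linearising both
circles at the shared anchor. Intervals spanning the linearisation cut are
not counted by default (a cut-then-compare workflow); the anchor is a
parameter, so the alternative convention is one argument away. Identical
orders of n genes have (n+1)(n−2)/2 intervals; the implementation is the
straightforward O(n²) window scan with a running min/max, checked against
an exhaustive-subset oracle — mitogenome orders are ≤ 40 genes, so nothing
faster is warranted.

The arthropod ground pattern ships as data (a Limulus-type ancestral
arrangement, with and without tRNAs) and is editable text. Published
retained-boundary and inversion counts for heavily reshuffled genomes
depend on unstated conventions (signed vs unsigned adjacencies, treatment
of boundaries interrupted by long non-coding regions); this implementation
reports the unsigned census and the full retained list so any convention
can be audited.

## Population scan

A column is variable iff it shows ≥ 2 states, a gap counting as a state; it
is an indel site iff a gap participates, else a substitution.
Transition/transversion status is tallied per distinct unordered base pair,
so a tri-allelic column contributes multiple pairs — the natural reading of
a pair-level "x% transitions" statistic. Parsimony-informative uses the
standard definition (≥ 2 states each in ≥ 2 haplotypes). Indel runs are
counted per column; run-level event counts can be derived from the site
list but windows and totals use columns.

Synonymous/nonsynonymous effect uses *observed* haplotype codons only,
never hypothetical mutants: the focal site is judged from observed codon
pairs that differ at that site alone, so a second variable position in the
same codon cannot confound it; when every observed pair is confounded the
pooled amino-acid set decides. Sites under overlapping annotations resolve
to the protein-coding gene.

The sliding window (defaults 200 columns, step 2) reports the
variable-column fraction per window; the trailing partial window is
dropped, and mean frequency is total variable sites / alignment length
exactly. Hotspots are merged runs of windows above a frequency quantile
(default 0.95), ranked by site density — an explicit rule standing in for
the common practice of eyeballing the top peaks, and flagged as the
implementation's own definition in reports.

Microsatellites are maximal perfect tandem repeats (motif length 1–6,
minimum repeat counts per motif length: 8/5/4/3/3/3), merged across
haplotypes by overlapping alignment spans and canonical motif rotation;
alleles are the distinct gap-free locus strings, so both repeat-number and
internal-sequence variants count. The control-region motif scan reports
poly-T runs (≥ 8 by default), microsatellites, and hairpins: maximal runs
of nested Watson–Crick pairs (stem ≥ 8) whose innermost pair encloses a
loop of 3–30 nt — wobble pairs and thermodynamic folding are deliberately
out of scope.

## Phylogenomic dataset preparation

Concatenation keeps alignment columns whose 0–9 confidence score exceeds
the threshold (default 5, i.e. score > 5 on the integer scale — "above
five" read strictly); atp8 is excluded by default as the gene most often
missing from sampled taxa; taxa absent from a gene are gap-padded and
recorded. Partition bookkeeping commutes with masking (a test).

Strand-bias exclusion is this package's concrete rendering of a one-line
criterion: per gene and taxon, G vs C counts at fourfold-degenerate third
positions are tested against a symmetric exact binomial; a gene is excluded
when p < α (default 0.05) in more than half of testable taxa. The full
per-taxon p-value table is emitted so the rule is auditable; genes without
degenerate sites are flagged and retained.

The slow–fast site rate is the summed within-group parsimony-step lower
bound: Σ over user-declared groups of (distinct non-gap states − 1). Groups
must be supplied — the method presumes predefined (ideally monophyletic)
groups, and guessing them would hide the analysis's main lever. Sites are
ranked into four equal-count quartiles and only Q2 ∪ Q3 retained; sites
tying a boundary rate are all retained (inclusion-biased and
deterministic). With fully distinct ranks exactly half the sites survive;
heavy tie blocks can retain more, to the point that a single rate class
retains everything.

Composition PCA is a centred PCA on per-taxon (A, C, G, T) proportions —
guidance for sampling compositionally homogeneous taxa, not an inference
method. Zero-variance input yields a flagged degenerate result.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (config, seed) using numpy's PCG64;
identical inputs are bit-identical across platforms. Counts are *placed*,
not drawn: the population generator picks exactly n substitution columns
(first k = round(ts_fraction·n) as transitions), exactly m indel columns
confined to non-coding spans, and programmed microsatellite repeat counts
per haplotype — so recovery tests assert equality, not closeness.

Defaults are the study conditions: a 20,460 nt, 35-feature template with 13
protein-coding genes, six LNRs and truncated stops on nad1/nad5 at
whole-genome composition targets A .321 / C .191 / G .193 / T .296; an
11-haplotype sample with 191 substitution columns at 87% transitions and
104 indel columns; three control-region microsatellite loci (a TCC array,
a hypervariable TA array spanning 10–56 repeats across seven alleles, and a
short TA array). Repeat-number variation necessarily adds gap columns
beyond the 104 programmed ones (99 under the defaults); the truth log
itemises them so scans reconcile exactly. Feature templates with overlaps
are clipped to abutting genes, since an assembled sequence cannot share
bases between features.

Codon pairs evolve by uniform single-base proposals with stop-creating
changes rejected and acceptance probabilities min(1, 1/ω) for synonymous
and min(1, ω) for nonsynonymous changes, which makes the realised
nonsynonymous:synonymous rate ratio target ω; the per-pair event log is
emitted. At the default divergence (~0.05/site before selection) NG86
recovers ω means within a few percent; recovery within 20% at
ω ∈ {0.05, 0.2, 1.0} is an acceptance test.

What the generators do **not** emulate: phylogenetic correlation among
haplotypes (changes are placed independently), rate heterogeneity along
the genome, named substitution models, recombination, sequencing error,
and alignment uncertainty. Passing recovery tests therefore demonstrates
that the *scanners and estimators* are correct bookkeeping-wise and
statistically calibrated on clean data — not that they are robust to
misalignment or model misspecification in field data.

## Problem sizes and numerical choices

The default test and acceptance runs use the full-genome scale the methods
target in practice — 20 kb genomes, 11-haplotype alignments, 500-codon
pairs with up to 200 replicates per ω target, rate-class fixtures of a few
hundred columns — because every stage is linear or near-linear and
completes in seconds. NG86 codon-pair difference counts are memoised per
unordered codon pair. Ties, degenerate inputs (empty tables, zero-variance
predictors, saturated JC corrections, single-member groups) return explicit
flags or documented errors rather than silent zeros.

## Known limitations

* tRNA/rRNA secondary structure, gene prediction and alignment computation
  are out of scope; alignments are consumed, not produced.
* Rearrangement *scenarios* (reversal/transposition reconstruction) are not
  inferred; only adjacency and common-interval statistics are computed.
* The divergence distances are uncorrected; for deep between-species
  nucleotide comparisons a model-corrected distance should be added.
* The hotspot rule (quantile + merge) is a reasonable formalisation, not a
  community standard; reports carry its parameters.
* Haplotype-network, population-structure and recombination inference are
  not provided.
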