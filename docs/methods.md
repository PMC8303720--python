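# Methods

This note documents the models, parameters and numerical choices behind
ampliscreen, and what the synthetic-data tests do and do not demonstrate
about real data.

## The screening problem

Resistance of fall armyworm to the Bt protein Cry1F is recessive and caused
by loss of function of the midgut receptor gene *SfABCC2*.  Truncating
mutations (nonsense and frameshift) are treated as resistance alleles: a
sample homozygous for one is predicted resistant; a sample heterozygous for
two *different* truncating alleles may be resistant if they lie in trans
(complementation), but short amplicon reads cannot phase them, so such
samples are reported as candidates, never as confirmed.  Missense changes
are surfaced for functional follow-up but never drive a phenotype verdict.

## Gene model

A gene is a plus-strand, gene-local sequence (1-based inclusive
coordinates) with ordered, non-overlapping exon intervals.  The CDS is the
exon concatenation; non-partial models must be complete ORFs (ATG start,
length divisible by 3, single terminal stop).  Models flagged `partial`
represent references with unsequenced `N` runs (e.g. an inter-scaffold
assembly gap); codons containing `N` translate to `X` and variants touching
them are left unclassified (`NONCODING`) rather than guessed.  Positions
before the first or after the last exon — including positions beyond the
recorded sequence — report as `outside`; only positions < 1 are errors.

## Amplicon simulator

`design_tiles` advances fixed-length amplicons (default 180 bp, the low end
of the panel's 180–200 bp range) by `amp_len − overlap` (default overlap
50 bp) and right-aligns the final tile, guaranteeing full coverage and
that any motif ≤ 50 bp is wholly contained in at least one tile.

`simulate_sample_reads` emulates *merged* single reads (the assay merges
paired 2×150 bp reads before analysis, so paired-end structure is not
modelled): per tile the read count is Poisson(mean_depth × efficiency),
each read is drawn from one of the sample's two haplotypes with equal
probability, and i.i.d. substitution errors are applied.  Haplotypes are
the reference with anchored edits applied; insertions lengthen reads,
deletions shorten them.  Indel sequencing errors are deliberately not
simulated — this keeps the genotyper's error model analysable (a wild-type
read can never be mis-scanned as mutant, because that would require an
insertion error) and is a documented limitation.

Cohort defaults are the study conditions the toolkit models: 41 samples
split 15/12/14 across three trapping locations (Lajas/Salinas/Santa
Isabel prefixes), mean per-tile depth 200 reads (the assay over-sequences
to > 100× per target, up to ~1000× for efficient targets), substitution
error 10⁻³ (merged high-quality short reads), a 2-bp GC insertion allele at
frequency 0.33 and a frameshift deletion at 0.32, genotypes drawn under
Hardy–Weinberg.  Per-tile efficiencies are lognormal with σ = 0.5
(normalised to mean 1) and **shared across samples**, since multiplex
primer efficiencies are reproducible between samples of one panel; the
lognormal shape and σ are modelling choices (only ">100×, up to 1000×" is
documented for the real assay).  All randomness flows from one seed;
per-sample generator seeds are derived from it and recorded in the truth
table.

What passing simulation tests shows: parameter recovery (allele frequency,
efficiency proportions, error rate) and correct thresholding under this
generative model.  What they do not show: robustness to indel sequencing
errors, primer dropout/artifacts, contamination or mapping ambiguity in
real data.

## k-mer flank genotyping

A read supports the mutant allele when the left 10-mer flank, the inserted
bases and the right 10-mer flank occur contiguously in that order; it
supports wild type when the flanks abut directly.  Each flank is allowed up
to 2 Hamming mismatches (any non-matching symbol, including `N`, counts);
the inserted bases must match exactly — the mismatch budget exists to
tolerate unknown flanking variation, and extending it to the inserted bases
would let wild-type sequence qualify as mutant.  Both orientations are
scanned (merged reads are unstranded); within an orientation a mutant match
takes precedence, and the first informative orientation wins.

Coverage is defined as *informative* reads (WT + MUT), i.e. the "matching
reads" of the protocol; uninformative reads never influence a call.  Call
rules: coverage < 40 ⇒ NoCall; mutant proportion ≤ 0.15 ⇒ SS (the carrier
rule is "more than 15%", so exactly 15% is susceptible); ≥ 0.85 ⇒ rr;
otherwise Sr.  Only the 15% carrier threshold is prescribed by the
protocol; the 85% homozygous boundary is this package's symmetric default —
robust to moderate allele-specific amplification — and is configurable, as
are all thresholds.

## Variant filter

Sample QC retains samples with mapping rate ≥ 0.80 (inclusive).  A record
survives iff QUAL > 40 (strict, matching "quality score greater than 40"),
at least ⌈0.25 × n_samples⌉ samples individually support it (total depth
≥ 8 and every called allele's depth ≥ 2), and the alternate allele
frequency across called genotypes is ≥ 0.05.  Attrition is reported per
stage and the stages sum to the input count.  Multi-allelic records are
dropped whole, not decomposed, by the bi-allelic selection step.  The
filter is idempotent and monotone in every threshold (property-tested).
The published accession-scale attrition (2006 → 1861 → 1333 variants)
requires the original read archive plus an external caller and is replaced
here by those property suites.

## Effect annotation and notation

Substitutions are classified by translating the affected codon(s);
insertions and deletions by whether the inserted/deleted length is
divisible by 3 (SHIFT vs INFRAME).  NON and SHIFT set `truncating`.
Notation: substitutions `refAA` + codon number + `altAA` (stops as `" *"`);
insertions append one residue per *started* codon of inserted sequence,
reconstructed from the uppercase-marked insertion plus reference context,
with `" *"` appended for frameshifts (the eventual premature stop is not
scanned for — the notation does not encode its position); in-frame
deletions list the deleted residues with no alternate (e.g. `CMV753`).
Codon displays keep context lowercase and changed bases uppercase.

The published mutation table labels in-frame deletions SHIFT; the
*table-compat* reporting mode (default in reports) maps
{SHIFT, INFRAME} → SHIFT so published tallies reproduce, while the
annotator's own vocabulary stays strict.  Three fixture rows are internally
inconsistent in the source table and are preserved verbatim but excluded
from formatter agreement checks: `A15 *` (a 3-bp deletion, in-frame by
arithmetic, printed as frameshift-with-stop) and `G13GG`/`G793VR`
(frameshift class without the stop marker).

Splice-region flagging uses a window of 3 exonic and 8 intronic bases
around each internal exon junction (the first two intronic bases being the
canonical donor/acceptor dinucleotide).  The window is configurable; the
source screen flagged a "predicted splice site region" without stating a
window, so the default follows common annotator practice.

## Cohort statistics

Allele frequency from genotype counts has two modes because the source
screen is internally inconsistent: its typeset formula doubles the
heterozygote count, `(2·ObsAa + Obsaa)/(2N)` (`mode="printed"`), and some
of its reported frequencies reproduce only under that form, while others
reproduce only under the standard estimator `(2·Obsaa + ObsAa)/(2N)`
(`mode="standard"`, the default).  Operations return full precision;
`format_frequency` applies explicit 4-decimal rounding or truncation
(the source mixes both conventions, so reproduction scripts pin the mode
per quantity).  Percent displays round half away from zero; under this
rule one of the source's location summaries (Salinas carriers, 41.67%)
renders 42 where it printed 41 — a source-side truncation not asserted
anywhere.

Concordance counts identical call labels over samples aligned by ID and is
symmetric.  Carrier summaries use all of a location's samples as the
denominator.

Genotype PCA mean-imputes missing calls per site (simple and standard for
genotype matrices; a drop-site alternative is available by masking),
mean-centres, and uses an SVD with a deterministic sign convention (largest
loading positive).  The association scan tests each site's 2×2 table of
allele counts by label class with Fisher's exact test — an exact
small-sample substitute for an unspecified logistic regression, chosen for
its behaviour at n ≈ 41.  Allele-count tests presuppose binomial allele
dosage: they are valid (conservative) for Hardy–Weinberg genotype
matrices, and the calibration property test asserts the one-sided validity
bound (empirical type-I error ≤ nominal + 3 SE), which is the guarantee an
exact conservative test actually makes.

## Problem sizes in the test suite

Simulation-backed tests use a compact synthetic gene (160 codons, two
exons, ~580 bp, 5 tiles) so cohorts of 200 samples at 100× depth run in
seconds; the full-size default gene (400 codons, 4 exons, 13 tiles) backs
the study-scale smoke tests at n = 41.  These sizes were chosen to keep the
statistical assertions well-powered (binomial 3·SE bounds at n ≥ 200 draws)
while remaining quick to iterate on.

## Known limitations

Single gene, plus strand, single isoform; no phasing, admixture or tree
building (external tools' territory); the k-mer genotyper handles insertion
alleles only; alleles expressed through aberrant splicing of repetitive
insertions outside the tiled regions are invisible to this design.
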