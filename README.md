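# ampliscreen

A Python toolkit for DNA-based monitoring of insecticide-resistance alleles
by targeted amplicon sequencing.  The motivating system is fall armyworm
(*Spodoptera frugiperda*) resistance to the Cry1F protein of Bt corn, which
is recessive and caused by loss-of-function mutations in the midgut ABC
transporter receptor gene *SfABCC2*: an individual with no intact receptor
allele — homozygous for a truncating (nonsense or frameshift) mutation, or
potentially carrying two different truncating mutations in trans — is
predicted resistant.  The toolkit is aimed at entomologists and resistance
managers who genotype field-collected moths with highly multiplexed tiled
amplicon panels (Hi-Plex style: 180–200 bp amplicons overlapping by 50 bp)
as a cheaper, more sensitive alternative to F1/F2 bioassay screens.

## What it does

* **Gene model** (`gene_model`): the target gene as sequence + exon
  intervals, with CDS assembly, translation, and gene→codon coordinate
  mapping.  FASTA/GFF3-subset I/O.
* **Read simulation** (`hiplex_sim`): tiled amplicon designs and synthetic
  diploid cohorts — merged single reads per tile, per-tile amplification
  efficiency skew, substitution sequencing error, Hardy–Weinberg genotypes —
  with a truth table for parameter-recovery testing.
* **k-mer genotyping** (`pgeno`): alignment-free genotyping of a known
  insertion from the two 10-mer sequences flanking the insertion point.
  Each flank tolerates up to 2 mismatches; the inserted bases must match
  exactly.  Calls require ≥ 40 informative reads; a carrier call requires
  strictly more than 15% mutant-supporting reads and a homozygous-mutant
  call at least 85%.
* **Variant filtering** (`variant_filter`): sample QC (mapping rate ≥ 80%)
  and the record cascade — QUAL > 40; per-sample depth ≥ 8 with every
  called allele's depth ≥ 2, in ≥ 25% of samples; alternate allele
  frequency ≥ 5% — then bi-allelic selection with SNP/indel tallies.
* **Effect annotation** (`effect_annotator`): codon-level classification
  (SYN/MISS/NON/SHIFT/INFRAME/intronic with splice-region flags) and the
  compact amino-acid-change notation used in resistance screening reports
  (e.g. `gat/gCGat → D740A *` for a frameshifting 2-bp insertion), plus a
  novelty filter against changes already seen in susceptible cDNAs.
* **Phenotype prediction** (`resistance`): the truncation rule —
  homozygous truncating ⇒ predicted resistant; two distinct heterozygous
  truncating alleles ⇒ complementation candidate (unphased); one ⇒ carrier.
* **Cohort statistics** (`popstats`): allele frequencies from genotype
  counts (standard estimator and the typeset variant used in the source
  screen), cross-method concordance, per-location carrier summaries,
  genotype PCA and a Fisher-exact per-site association scan.

A `click` CLI (`ampliscreen simulate|pgeno|filtervcf|annotate|predict|stats|run`)
wraps the library; `run` executes the configured end-to-end pipeline
deterministically from a single seed.

## Worked example

The package ships a 41-sample cohort fixture (TaqMan vs k-mer genotype calls
for the *SfABCC2mut* GC-insertion allele, with trapping locations parsed
from sample-name prefixes) and a 24-row mutation table.

```sh
ampliscreen stats --fixture table1 --mode printed
```

prints (abridged):

```json
{
  "concordance": {"n_concordant": 30, "n_total": 41, "rate": 0.7317},
  "kmer":   {"n_het": 8, "n_hom": 6, "allele_frequency": 0.2683,
             "carriers_by_location": {"Lajas": {"pct_carriers": 53, "pct_het": 33, "pct_hom": 20}}},
  "taqman": {"n_het": 7, "n_hom": 9,
             "carriers_by_location": {"Lajas": {"pct_carriers": 53, "pct_het": 20, "pct_hom": 33},
                                      "Santa Isabel": {"pct_hom": 21}}}
}
```

The two genotyping methods agree on 30 of 41 samples (73%); the k-mer
column's 8 heterozygotes and 6 homozygotes give an insertion-allele
frequency of 0.2683 under the typeset formula; carriers concentrate in
Lajas (53%, of which 33% homozygous — the individuals predicted
Cry1F-resistant).

The same numbers are available programmatically:

```python
from ampliscreen.fixtures import cohort_table_from_table1
from ampliscreen.popstats import carrier_summary, concordance_from_table

table = cohort_table_from_table1()
concordance_from_table(table, "taqman", "kmer").rate   # 0.7317...
carrier_summary(table, "taqman").loc["Lajas", "pct_hom"]  # 33
```

And a full synthetic round trip — simulate a cohort, genotype it, check the
truth table:

```sh
ampliscreen simulate --out sim --n-samples 41 --seed 7
ampliscreen pgeno --site sim/sites.tsv --fastq-dir sim/fastq --out calls.tsv
```

At the default study-scale settings (mean depth 200 per tile, 0.1%
substitution error) every call matches the simulated truth.

## Limitations

Single-gene, plus-strand models only; insertion alleles only for the k-mer
genotyper; variant *calling* is out of scope (the filter consumes any
caller's VCF); the simulator draws substitution errors only and does not
model primer thermodynamics, chimeras or quality-score profiles.  See
`docs/methods.md` for the full model description and design rationale.
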