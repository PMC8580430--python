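# Methods

## The model

The package treats the genomic tRNA gene copy number t<sub>ij</sub>
(anticodon *j* of amino acid *i*) as a proxy for the cytoplasmic abundance
of the corresponding tRNA. Translation efficiency of an mRNA then depends on
how well its codon usage matches that pool. Three indices decompose the
match:

* **CSI** isolates synonymous-codon choice. Within each amino-acid family
  the codon counts and the tRNA copy numbers are separately normalized to
  frequencies (CF<sub>ij</sub> and TF<sub>ij</sub>), which removes all
  amino-acid composition signal; the pooled Pearson correlation across
  families is the index.
* **TAAI** isolates amino-acid composition: the Pearson correlation over
  the 20 amino acids between a gene's amino-acid counts and the genomic
  totals T<sub>i</sub>. It is scale-invariant, so counts and frequencies
  give the same value.
* **tAI** mixes both levels: each codon receives an availability weight
  W<sub>c</sub> = Σ (1 − s<sub>type</sub>) t<sub>a</sub> over the anticodons
  *a* that can decode it, normalized so max w = 1, and a gene's tAI is the
  geometric mean of its codons' weights. Codons no anticodon decodes take
  the geometric mean of the nonzero weights (the standard missing-value
  convention, which keeps the aggregate finite and neutral).

### Decoding relations

Anticodons are stored in the DNA alphabet, 5'→3', with string position 0 as
tRNA base 34 (the wobble position). Under Watson–Crick rules an anticodon
reads exactly its reverse complement. Extended rules add, at the codon's
third position: G34:U3 and U34:G3 wobble (independently toggleable, both on
by default — both are chemically G:U pairs) and inosine pairing after ADAT
editing of A34 (I:U, I:C, I:A). Two hard constraints: decoding never
produces a stop codon and never crosses an amino-acid family — a wobble
expansion that would change the encoded amino acid is discarded, because
every family-normalized statistic would otherwise be corrupted.

With the sea cucumber's 16 absent anticodons, extended decoding covers 13;
the three Val codons GTT/GTC/GTA stay orphaned (Val retains only the CAC
anticodon, which cannot wobble). Switching U34:G3 off reduces coverage to
12/16 — the Arg codon CGG loses its only alternative reader. This coverage
arithmetic is enumerated exhaustively in the tests.

### Equal allocation and the two CSI variants

For extended-rule analyses codon counts are re-expressed per anticodon by
splitting each codon's count equally among the present anticodons that can
decode it; orphan codons are reported separately, never silently dropped, so
mass is conserved. Per-gene CSI defaults to Watson–Crick pairing: the index
is defined as the correlation of synonymous codon frequencies with their
cognate isoacceptor frequencies, and the equal split — applied to every
codon, not only the orphaned ones — redistributes mass away from the cognate
reader and measurably caps the correlation near 0.6 even for perfectly
adapted genes. The extended variant therefore serves the transcriptome-level
question ("is expressed codon mass decodable by the pool?"), where
reassigning the mass of codons whose cognate anticodons are missing raises
the pooled correlation, as the orphan-coverage analysis predicts.

Families with a single synonymous codon (Met, Trp) are excluded from CSI by
default: their forced (1, 1) points carry no information and inflate r. A
flag restores them. A gene needs at least 3 pooled points with variance on
both axes; otherwise the index is flagged undefined rather than NaN.

### Species-specific tAI

The wobble penalties s<sub>type</sub> default to the classical values
(I:U = 0, G:U = 0.41, I:C = 0.28, I:A = 0.9999, U:G = 0.68; Watson–Crick
pairs are never penalized). `stai_optimize` tunes them per species by
deterministic coordinate ascent on a 0.05-step grid, maximizing the Spearman
correlation between per-gene tAI and a user-chosen objective (typically
expression). Ties prefer the smaller penalty; the scan order of the four
wobble classes is fixed, so the result is reproducible. A penalty class that
carries almost no decoding mass (I:A under realistic censuses) barely moves
the objective and is not identifiable — recovery guarantees in the tests are
therefore restricted to classes carrying at least 10% of decoding mass.

## Statistics

Pearson p-values use the t-distribution with n−2 df, two-sided. The
intron/intergenic density contrast is a χ² goodness-of-fit of the two locus
counts against the span-proportional expectation (1 df, no continuity
correction); the ratio is reported as intronic:intergenic normalized to 1:x.
Enrichment is a one-sided hypergeometric upper tail per category with BH FDR
across tested categories (EASE-style overlap-minus-one available as an
option); the background defaults to all genes with a defined index value.
Pathway contrasts use the Wilcoxon rank-sum test — normal approximation with
tie correction by default, exact enumeration for small groups. BH-adjusted
values are monotone in the ranked raw p and reproduce the step-up rejection
set at any level; note that re-running the adjustment on already-adjusted
values is *not* an identity, which is why the tests check rejection-set
idempotence rather than value idempotence.

The ecology correlation pairs per-amino-acid tRNA totals with particulate
amino-acid concentrations by identity. Acid hydrolysis of particulate
protein deamidates Asn→Asp and Gln→Glu, so when the supplied table has 18 or
fewer amino acids the tRNA totals for Asn and Gln are pooled into Asp and
Glu before correlating (auto-detected, overridable).

## The synthetic-data generator

`SimulationConfig` plants known truth and its defaults mirror the study
system: 1032 total tRNA gene copies; the `sea_cucumber` preset removes the 16
absent anticodons; about 4.7% of tRNA loci fall in introns (49/1032) with
the intron:intergenic span ratio set so the planted density contrast is
1:2.9. Per-amino-acid totals follow a Dirichlet-multinomial (α = 2 — broad
but not degenerate family totals), split within families by a uniform
Dirichlet. Amino acids are drawn ∝ T<sub>i</sub><sup>γ</sup> and synonymous
codons ∝ TF<sub>ij</sub><sup>β</sup>; γ = 1 reproduces pool-proportional
composition, β = 0 is the synonymous-neutral control, and β = 4 the
strong-adaptation condition used in the recovery checks. Gene lengths are
log-normal (median 300 codons, σ = 0.6, clipped to 50–3000). Expression is
log-normal with a Gaussian-copula rank coupling (default ρ = 0.3) to each
gene's tAI. The particulate-amino-acid vector is an affine transform of the
(hydrolysis-merged, 18-element) tRNA totals plus Gaussian noise whose
standard deviation is set from the target correlation, with a positive
offset instead of clipping so the target is not attenuated.

All stages draw from substreams seeded by (seed, stage name), so adding a
stage never perturbs earlier stages and regeneration is byte-identical.

What the generator does **not** emulate: mutational biases and GC content,
isochores, codon autocorrelation along a gene, alternative splicing beyond
one transcript per gene, pseudogenes and SINE look-alikes in the tRNA table,
and measurement noise in expression. Passing recovery tests therefore show
that the estimators invert the generator's statistical structure, not that
real genomes satisfy that structure.

## Numerical and design choices

* Coordinates are 1-based inclusive everywhere; tRNAscan-SE minus-strand
  records (begin > end) are normalized on input.
* A tRNA locus is intronic only if fully inside the gene-level exon-union
  complement of a protein-coding gene; any exon overlap makes it exonic.
  Strand is ignored by default (`stranded=True` restricts to same-strand
  hosts), since annotation strand reliability varies across assemblies.
* CDS codons containing N are excluded and tallied; internal stops truncate
  with a warning by default (real annotations contain broken models), with
  strict and skip modes available. The terminal stop never counts; ATG
  counts as Met.
* Expression weighting uses FPM, not FPKM/TPM: a long transcript engages
  multiple ribosomes simultaneously, so its full fragment mass is the
  relevant weight. Multi-sample tables are averaged arithmetically after
  per-sample normalization; a gene's fragments are split equally among its
  isoforms.
* Extreme-tail selection uses floor(n·fraction) per tail with boundary ties
  broken lexicographically by gene id, making selections reproducible.
* Relative ranks are fractional percentiles in (0, 1], ties averaged;
  undefined index values are excluded and flagged.
* Result writers emit fixed column order and 6-significant-digit floats, so
  re-runs are byte-identical and diffable.

## Problem sizes in the test suite

The recovery checks run at 120–200 genes of 250–300 codons, the replicate
calibrations at 50 seeds, and the exhaustive hypergeometric comparison at
all population sizes up to 30 plus a 1500-case sample up to 60 — sizes at
which every targeted effect is decisively visible while the whole suite
stays fast enough to run on every commit.

## Known limitations

* The species-specific tAI optimizer is a from-scratch design (grid
  coordinate ascent on four penalty classes); published stAI software may
  weight or constrain penalties differently, so absolute stAI values are not
  interchangeable across tools — ranks within a genome are the robust
  output.
* The equal-allocation extended CSI is coarse by construction (see above);
  use it for pool-coverage questions, not for ranking genes.
* Enrichment assumes a pre-flattened gene→category map; ontology-level
  filtering (e.g. "level 3" GO terms) is the caller's responsibility.
* With heavy ties or tiny families the Pearson-based indices go undefined by
  design; downstream summaries report how many genes were excluded.
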