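# trnacoadapt

Co-adaptation analysis between genomic tRNA content and codon usage, built
around the biology of the sea cucumber *Apostichopus japonicus* but usable
for any genome with a tRNA annotation and a CDS set.

Because cellular tRNA concentrations track genomic tRNA gene copy numbers,
the copy-number census is a usable proxy for the tRNA pool that translates a
transcriptome. This package quantifies how well coding sequences match that
pool at three levels:

* **Synonymous-codon level (CSI).** For amino acid *i* with *n<sub>i</sub>*
  isoacceptors, the genomic isoacceptor frequency is
  TF<sub>ij</sub> = t<sub>ij</sub> / Σ<sub>j</sub> t<sub>ij</sub> and a
  gene's synonymous codon frequency is
  CF<sub>ij</sub> = c<sub>ij</sub> / Σ<sub>j</sub> c<sub>ij</sub>.
  The CSI is the Pearson correlation of the pooled (TF<sub>ij</sub>,
  CF<sub>ij</sub>) points across families. Transcriptome-wide, codon counts
  are weighted by expression (FPM — fragments per million mapped reads,
  deliberately not length-normalized) before the family normalization:
  TCF<sub>ij</sub> = Σ<sub>k</sub> e<sub>k</sub> c<sub>ijk</sub> /
  Σ<sub>j</sub> Σ<sub>k</sub> e<sub>k</sub> c<sub>ijk</sub>.
* **Amino-acid level (TAAI).** Pearson correlation between a gene's
  amino-acid usage and the per-amino-acid tRNA copy totals
  T<sub>i</sub> = Σ<sub>j</sub> t<sub>ij</sub>.
* **Combined (tAI / stAI).** The classical tRNA adaptation index: the
  count-weighted geometric mean of per-codon weights
  w<sub>c</sub> ∝ Σ<sub>a→c</sub> (1 − s<sub>pairing(a,c)</sub>) t<sub>a</sub>,
  summed over the anticodons that can decode codon *c*. The
  species-specific variant tunes the wobble penalties *s* by maximizing the
  Spearman correlation of tAI with an objective such as expression.

Decoding relations go beyond Watson–Crick pairing: G:U wobble at the
anticodon's position 34 (both orientations) and inosine pairing after ADAT
editing of A34 (I:U, I:C, I:A) are modelled explicitly, never crossing
amino-acid families. This matters for genomes like the sea cucumber's, where
tRNA genes for 16 anticodons are absent yet all but the three Val codons
GTT/GTC/GTA remain decodable.

Downstream statistics cover the genomic context of tRNA loci (intronic vs
intergenic density, χ² test), top/bottom-tail category enrichment
(hypergeometric + Benjamini–Hochberg FDR), pathway contrasts (Wilcoxon
rank-sum), and the ecological correlation between per-amino-acid tRNA
content and the amino-acid composition of particulate organic matter — the
deposit-feeder's food supply.

A seeded synthetic-data generator produces self-consistent bundles (census,
CDS FASTA, GFF3 layout, expression, categories, particulate amino acids)
with recorded ground truth, so every stage is testable without downloads.

## Worked example

```python
from trnacoadapt import (SimulationConfig, write_bundle, build_census,
                         isoacceptor_frequencies, count_codons,
                         build_profiles, paa_correlation)
from trnacoadapt.io_formats import read_trna_table, read_cds_fasta, read_paa_table

bundle = write_bundle(SimulationConfig.sea_cucumber(seed=7, n_genes=100), "demo")
records = read_trna_table(bundle.trna_table)      # tRNAscan-SE dialect
census = build_census(records)
tf = isoacceptor_frequencies(census)
seqs, qc = read_cds_fasta(bundle.cds_fasta)
counts = [count_codons(s, g) for g, s in sorted(seqs.items())]
profiles = build_profiles(counts, census, tf)

print(f"tRNA gene copies: {census.total_copies}")
print(f"median CSI : {profiles['csi'].median():.3f}  "
      f"({100 * (profiles['csi'] > 0).mean():.1f}% positive)")
print(f"median TAAI: {profiles['taai'].median():.3f}")
print(f"median tAI : {profiles['tai'].median():.3f}")
res = paa_correlation(census, read_paa_table(bundle.paa))
print(f"tRNA content vs food amino acids: r={res.r:.2f} (n={res.n})")
```

Output:

```
tRNA gene copies: 1032
median CSI : 0.931  (100.0% positive)
median TAAI: 0.947
median tAI : 0.331
tRNA content vs food amino acids: r=0.76 (n=18)
```

The bundle plants strong codon adaptation (codon choice ∝ TF⁴), so nearly
every synthetic gene correlates positively with the tRNA pool at both the
synonymous-codon and the amino-acid level; the particulate-amino-acid vector
was generated with a target correlation of 0.7 to the tRNA totals, and the
estimate lands nearby.

The same pipeline runs from the shell:

```sh
trnacoadapt simulate --out demo --seed 7 --preset sea-cucumber
trnacoadapt run --config config.yaml --out results/
```

where `config.yaml` names the input files (`trna_table`, `cds`, optionally
`gff3`, `expression`, `categories`, `paa`) and options (`rule`, `extremes`,
`index`). Outputs are deterministic TSV tables plus a run manifest with
input checksums.

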