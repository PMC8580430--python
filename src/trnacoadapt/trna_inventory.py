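"""tRNA census, isoacceptor frequencies and genomic-context statistics.

The census records the genomic copy number t_ij of every sense anticodon
(explicit zeros included).  Isoacceptor frequencies normalize copy numbers
within each amino-acid family: TF_ij = t_ij / sum_j t_ij.  Context statistics
classify tRNA loci as intronic / exonic / intergenic against gene models and
test whether the intronic tRNA density departs from the span-proportional
expectation (chi-square goodness of fit, 1 df).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from scipy import stats

from .genetic_code import CODON_TO_AA, SENSE_ANTICODONS, wc_codon
from .io_formats import GeneModel, TrnaGeneRecord

__all__ = [
    "TrnaCensus",
    "IsoacceptorFrequencies",
    "ContextTally",
    "build_census",
    "isoacceptor_frequencies",
    "classify_context",
    "density_contrast",
]

#: anticodon -> one-letter amino acid of its Watson-Crick codon
ANTICODON_TO_AA: Dict[str, str] = {
    a: CODON_TO_AA[wc_codon(a)] for a in sorted(SENSE_ANTICODONS)
}


@dataclass(frozen=True)
class TrnaCensus:
    """Genomic tRNA copy numbers per anticodon, with per-amino-acid totals."""

    t: Mapping[str, int]
    species: str = ""

    def __post_init__(self) -> None:
        missing = SENSE_ANTICODONS - set(self.t)
        if missing:
            raise ValueError(f"census lacks anticodons: {sorted(missing)[:5]}")
        if any(v < 0 for v in self.t.values()):
            raise ValueError("negative copy number")

    def totals_by_aa(self) -> Dict[str, int]:
        """T_i = sum_j t_ij per amino acid (one-letter keys)."""
        totals: Dict[str, int] = {}
        for a, count in self.t.items():
            aa = ANTICODON_TO_AA[a]
            totals[aa] = totals.get(aa, 0) + int(count)
        return totals

    @property
    def total_copies(self) -> int:
        return int(sum(self.t.values()))

    def present_anticodons(self) -> frozenset:
        return frozenset(a for a, v in self.t.items() if v > 0)


@dataclass(frozen=True)
class IsoacceptorFrequencies:
    """TF_ij per anticodon; amino acids with zero total copies are undefined."""

    tf: Mapping[str, float]
    undefined_aas: frozenset = frozenset()

    def __getitem__(self, anticodon: str) -> float:
        return self.tf[anticodon]


def build_census(records: Iterable[TrnaGeneRecord],
                 species: str = "") -> TrnaCensus:
    """Count tRNA gene copies per anticodon (explicit zeros for all 61)."""
    t = {a: 0 for a in sorted(SENSE_ANTICODONS)}
    for rec in records:
        t[rec.anticodon] += 1
    return TrnaCensus(t=t, species=species)


def isoacceptor_frequencies(census: TrnaCensus) -> IsoacceptorFrequencies:
    """TF_ij = t_ij / T_i within each amino-acid family.

    Families with T_i = 0 are reported as undefined rather than zero; an
    all-zero census is an error.
    """
    totals = census.totals_by_aa()
    if all(v == 0 for v in totals.values()):
        raise ValueError("all-zero census: no isoacceptor frequencies")
    tf: Dict[str, float] = {}
    undefined = set()
    for a, count in census.t.items():
        aa = ANTICODON_TO_AA[a]
        if totals[aa] > 0:
            tf[a] = count / totals[aa]
        else:
            undefined.add(aa)
    return IsoacceptorFrequencies(tf=tf, undefined_aas=frozenset(undefined))


@dataclass
class ContextTally:
    """tRNA locus counts and genomic span (bp) by context class."""

    counts: Dict[str, int] = field(default_factory=lambda: {
        "intronic": 0, "intergenic": 0, "exonic": 0})
    spans: Dict[str, int] = field(default_factory=lambda: {
        "intronic": 0, "intergenic": 0, "exonic": 0})


def _merge(intervals: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    merged: List[Tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _total(intervals: List[Tuple[int, int]]) -> int:
    return sum(e - s + 1 for s, e in intervals)


def _contains(intervals: List[Tuple[int, int]], s: int, e: int) -> bool:
    return any(a <= s and e <= b for a, b in intervals)


def _overlaps(intervals: List[Tuple[int, int]], s: int, e: int) -> bool:
    return any(a <= e and s <= b for a, b in intervals)


def classify_context(records: Iterable[TrnaGeneRecord],
                     gene_models: Iterable[GeneModel],
                     seq_lengths: Optional[Mapping[str, int]] = None,
                     stranded: bool = False) -> ContextTally:
    """Classify each tRNA locus as exonic, intronic or intergenic.

    A locus overlapping any exon (union over transcripts) of a protein-coding
    gene is exonic; a locus fully inside a gene span but not touching an exon
    is intronic; anything else is intergenic.  Strand is ignored by default
    (``stranded=True`` restricts the genic classes to same-strand host genes).
    Span lengths per class are computed from the same gene models; sequence
    lengths default to the maximum coordinate seen per sequence.
    """
    records = list(records)
    models = [m for m in gene_models if m.biotype == "protein_coding"]

    by_seq_exons: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    by_seq_genes: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    seq_ids = set()
    for m in models:
        seq_ids.add(m.seq_id)
        for strand in (("+", "-") if not stranded else (m.strand,)):
            key = (m.seq_id, strand)
            by_seq_genes.setdefault(key, []).append((m.start, m.end))
            by_seq_exons.setdefault(key, []).extend(m.exon_union())

    missing = sorted({r.seq_id for r in records}
                     - seq_ids - set(seq_lengths or {}))
    if missing:
        raise ValueError(f"tRNA records on unknown sequences: {missing}")

    # per-sequence merged unions, unstranded for the span bookkeeping
    exon_union: Dict[str, List[Tuple[int, int]]] = {}
    gene_union: Dict[str, List[Tuple[int, int]]] = {}
    for (seq, _strand), ivs in by_seq_exons.items():
        exon_union.setdefault(seq, []).extend(ivs)
    for (seq, _strand), ivs in by_seq_genes.items():
        gene_union.setdefault(seq, []).extend(ivs)
    exon_union = {s: _merge(v) for s, v in exon_union.items()}
    gene_union = {s: _merge(v) for s, v in gene_union.items()}

    if seq_lengths is None:
        seq_lengths = {}
        for r in records:
            seq_lengths.setdefault(r.seq_id, 0)
            seq_lengths[r.seq_id] = max(seq_lengths[r.seq_id], r.end)
        for m in models:
            seq_lengths.setdefault(m.seq_id, 0)
            seq_lengths[m.seq_id] = max(seq_lengths[m.seq_id], m.end)

    tally = ContextTally()
    for seq, length in seq_lengths.items():
        exonic_bp = _total(exon_union.get(seq, []))
        genic_bp = _total(gene_union.get(seq, []))
        tally.spans["exonic"] += exonic_bp
        tally.spans["intronic"] += genic_bp - exonic_bp
        tally.spans["intergenic"] += max(length - genic_bp, 0)

    for r in records:
        if stranded:
            exons = _merge(by_seq_exons.get((r.seq_id, r.strand), []))
            genes = _merge(by_seq_genes.get((r.seq_id, r.strand), []))
        else:
            exons = exon_union.get(r.seq_id, [])
            genes = gene_union.get(r.seq_id, [])
        if _overlaps(exons, r.begin, r.end):
            tally.counts["exonic"] += 1
        elif _contains(genes, r.begin, r.end):
            tally.counts["intronic"] += 1
        else:
            tally.counts["intergenic"] += 1
    return tally


def density_contrast(tally: ContextTally) -> Tuple[float, float, float]:
    """Intronic vs intergenic tRNA density contrast.

    Returns ``(ratio, chi2, p)`` where ``ratio`` is the intergenic:intronic
    density quotient (a value of 2.9 reads "1 : 2.9"), and the chi-square
    statistic tests the observed locus counts against the span-proportional
    expectation (1 df, no continuity correction).
    """
    n_in, n_ig = tally.counts["intronic"], tally.counts["intergenic"]
    s_in, s_ig = tally.spans["intronic"], tally.spans["intergenic"]
    if s_in <= 0 or s_ig <= 0:
        raise ValueError("both intronic and intergenic spans must be positive")
    total = n_in + n_ig
    if total == 0:
        raise ValueError("no intronic or intergenic tRNA loci")
    d_in, d_ig = n_in / s_in, n_ig / s_ig
    ratio = float("inf") if d_in == 0 else d_ig / d_in
    expected = [total * s_in / (s_in + s_ig), total * s_ig / (s_in + s_ig)]
    chi2, p = stats.chisquare([n_in, n_ig], f_exp=expected)
    return ratio, float(chi2), float(p)
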