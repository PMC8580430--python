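"""Codon and amino-acid usage accounting, per gene and transcriptome-wide.

Per-gene synonymous codon frequencies normalize codon counts within each
amino-acid family (CF_ij = c_ij / sum_j c_ij).  Transcriptome codon
frequencies weight each gene's counts by its expression level before the
family normalization (TCF_ij = sum_k e_k c_ijk / sum_j sum_k e_k c_ijk).
Expression is measured as FPM — fragments of a transcript per million mapped
reads, deliberately not length-normalized: a long mRNA engages multiple
ribosomes (and hence tRNAs) simultaneously, so its full fragment mass is the
relevant weight when relating codon usage to tRNA availability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

from .genetic_code import (
    AA_TO_CODONS,
    CODON_TO_AA,
    SENSE_CODONS,
    STOP_CODONS,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GeneCodonCounts",
    "TranscriptomeUsage",
    "count_codons",
    "synonymous_frequencies",
    "compute_fpm",
    "allocate_isoform_reads",
    "transcriptome_codon_frequencies",
    "amino_acid_usage",
    "weighted_aa_usage",
]


@dataclass
class GeneCodonCounts:
    """Codon counts c_ij for one gene (sense codons only)."""

    gene_id: str
    c: Dict[str, int] = field(default_factory=dict)
    n_excluded: int = 0  # codons containing N
    truncated_at_stop: bool = False

    @property
    def L(self) -> int:
        """Total codons counted."""
        return sum(self.c.values())

    def aa_counts(self) -> Dict[str, int]:
        """A_i = sum_j c_ij per amino acid."""
        out: Dict[str, int] = {}
        for codon, n in self.c.items():
            aa = CODON_TO_AA[codon]
            out[aa] = out.get(aa, 0) + n
        return out


def count_codons(cds: str, gene_id: str = "",
                 on_internal_stop: str = "truncate") -> GeneCodonCounts:
    """Count sense codons of a CDS.

    The terminal stop codon is excluded; codons containing N are excluded and
    tallied.  An in-frame internal stop is handled per ``on_internal_stop``:
    ``truncate`` (default) counts codons before it and warns, ``error``
    raises, ``skip`` drops the stop codon and keeps counting.
    """
    cds = cds.upper()
    counts = GeneCodonCounts(gene_id=gene_id)
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i:3 * i + 3]
        if codon in STOP_CODONS:
            if i == n_codons - 1:
                break  # terminal stop
            if on_internal_stop == "error":
                raise ValueError(f"{gene_id}: internal stop at codon {i + 1}")
            if on_internal_stop == "truncate":
                logger.warning("%s: internal stop at codon %d; truncating",
                               gene_id, i + 1)
                counts.truncated_at_stop = True
                break
            continue  # skip
        if "N" in codon:
            counts.n_excluded += 1
            continue
        counts.c[codon] = counts.c.get(codon, 0) + 1
    return counts


def synonymous_frequencies(counts: GeneCodonCounts) -> Dict[str, float]:
    """CF_ij = c_ij / A_i within each amino-acid family observed in the gene.

    Families with A_i = 0 are absent from the result (undefined); within an
    observed family every synonymous codon gets a frequency, zeros included.
    """
    aa_totals = counts.aa_counts()
    cf: Dict[str, float] = {}
    for aa, total in aa_totals.items():
        if total == 0:
            continue
        for codon in AA_TO_CODONS[aa]:
            cf[codon] = counts.c.get(codon, 0) / total
    return cf


def compute_fpm(fragments: Mapping[str, float]) -> Dict[str, float]:
    """Fragments per million mapped reads: fpm_t = f_t * 1e6 / sum f."""
    total = float(sum(fragments.values()))
    if total <= 0:
        raise ValueError("total fragment count must be positive")
    if any(v < 0 for v in fragments.values()):
        raise ValueError("negative fragment count")
    return {t: v * 1e6 / total for t, v in fragments.items()}


def allocate_isoform_reads(gene_fragments: float,
                           n_transcripts: int) -> List[float]:
    """Split a gene's fragment count equally among its transcripts."""
    if n_transcripts < 1:
        raise ValueError("a gene must have at least one transcript")
    return [gene_fragments / n_transcripts] * n_transcripts


@dataclass
class TranscriptomeUsage:
    """Expression-weighted transcriptome codon usage.

    ``w`` holds W_ij = sum_k e_k c_ijk; ``tcf`` normalizes W within each
    amino-acid family (families with zero weighted mass are absent).
    """

    w: Dict[str, float]
    tcf: Dict[str, float]


def transcriptome_codon_frequencies(
        all_counts: Iterable[GeneCodonCounts],
        e: Optional[Mapping[str, float]] = None) -> TranscriptomeUsage:
    """Pool per-gene codon counts with expression weights into TCF_ij.

    If ``e`` is None every gene gets unit weight (the result then equals the
    pooled CF of summed counts).  ``e`` may map a gene to a single value or a
    sequence of per-sample values, which are arithmetically averaged first.
    """
    w = {codon: 0.0 for codon in SENSE_CODONS}
    for gc in all_counts:
        if e is None:
            ek = 1.0
        else:
            if gc.gene_id not in e:
                raise ValueError(f"no expression value for gene {gc.gene_id}")
            val = e[gc.gene_id]
            ek = (float(sum(val)) / len(val)
                  if isinstance(val, Sequence) and not isinstance(val, str)
                  else float(val))
        if ek < 0:
            raise ValueError(f"negative expression for gene {gc.gene_id}")
        for codon, n in gc.c.items():
            w[codon] += ek * n

    tcf: Dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        family_total = sum(w[c] for c in codons)
        if family_total > 0:
            for c in codons:
                tcf[c] = w[c] / family_total
    return TranscriptomeUsage(w=w, tcf=tcf)


def amino_acid_usage(counts: GeneCodonCounts) -> Dict[str, int]:
    """Per-amino-acid codon totals of one gene (all 20 keys, zeros kept)."""
    usage = {aa: 0 for aa in AA_TO_CODONS}
    usage.update(counts.aa_counts())
    return usage


def weighted_aa_usage(all_counts: Iterable[GeneCodonCounts],
                      e: Optional[Mapping[str, float]] = None
                      ) -> Dict[str, float]:
    """Transcriptome amino-acid usage, each gene weighted by expression."""
    usage = {aa: 0.0 for aa in AA_TO_CODONS}
    for gc in all_counts:
        if e is None:
            ek = 1.0
        else:
            val = e[gc.gene_id]
            ek = (float(sum(val)) / len(val)
                  if isinstance(val, Sequence) and not isinstance(val, str)
                  else float(val))
        if ek < 0:
            raise ValueError(f"negative expression for gene {gc.gene_id}")
        for aa, n in gc.aa_counts().items():
            usage[aa] += ek * n
    return usage
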