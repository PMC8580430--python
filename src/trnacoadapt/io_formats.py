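"""Readers and writers for the pipeline's external formats.

Input side: tRNAscan-SE legacy tabular output (or a minimal two-column
anticodon/count TSV), CDS FASTA, GFF3 gene models, and plain TSV tables for
expression, gene categories and particulate-amino-acid concentrations.
Output side: deterministic TSV result tables.  All genomic coordinates are
1-based inclusive internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import gffutils
import pandas as pd
from Bio import SeqIO

from .genetic_code import (
    AA3_TO_AA1,
    SENSE_ANTICODONS,
    STOP_CODONS,
    CODON_TO_AA,
    wc_codon,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TrnaGeneRecord",
    "GeneModel",
    "CdsQc",
    "read_trna_table",
    "read_cds_fasta",
    "read_gff3",
    "read_expression_table",
    "read_category_map",
    "read_paa_table",
    "write_results",
]


@dataclass(frozen=True)
class TrnaGeneRecord:
    """One tRNA gene locus from an annotation run."""

    seq_id: str
    begin: int  # 1-based inclusive, begin <= end after normalization
    end: int
    strand: str  # '+' or '-'
    isotype: str  # three-letter amino-acid code, e.g. 'Asp'
    anticodon: str  # DNA alphabet, 5'->3'
    score: float = 0.0
    intron: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.begin <= 0 or self.end <= 0:
            raise ValueError("coordinates must be positive")
        if self.begin > self.end:
            raise ValueError("begin must not exceed end after normalization")
        if self.anticodon not in SENSE_ANTICODONS:
            raise ValueError(
                f"anticodon {self.anticodon!r} does not read a sense codon")


@dataclass
class GeneModel:
    """A protein-coding (or other) gene with its transcripts' exon intervals."""

    gene_id: str
    seq_id: str
    strand: str
    start: int
    end: int
    transcripts: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)
    biotype: str = "protein_coding"

    def exon_union(self) -> List[Tuple[int, int]]:
        """Merged union of all exons across transcripts (sorted, disjoint)."""
        intervals = sorted(
            iv for exons in self.transcripts.values() for iv in exons)
        merged: List[Tuple[int, int]] = []
        for s, e in intervals:
            if merged and s <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged


@dataclass
class CdsQc:
    """Per-gene QC flags attached by :func:`read_cds_fasta`."""

    length_not_multiple_of_3: bool = False
    internal_stop: bool = False
    n_count: int = 0

    @property
    def clean(self) -> bool:
        return not (self.length_not_multiple_of_3 or self.internal_stop
                    or self.n_count)


_SPECIAL_ISOTYPES = {
    # iMet tRNAs are merged into Met; selenocysteine has no standard-code
    # codon family and is dropped.
    "iMet": "Met",
    "fMet": "Met",
    "SeC": None,
    "Sec": None,
    "SeC(e)": None,
    "Sup": None,
    "Und": None,
    "Undet": None,
}


def _normalize_isotype(isotype: str) -> Optional[str]:
    if isotype in _SPECIAL_ISOTYPES:
        mapped = _SPECIAL_ISOTYPES[isotype]
        if mapped != isotype:
            logger.warning("isotype %s -> %s", isotype, mapped or "dropped")
        return mapped
    return isotype if isotype in AA3_TO_AA1 else None


def _record_from_fields(seq_id: str, begin: int, end: int, isotype: str,
                        anticodon: str, score: float,
                        intron: Optional[Tuple[int, int]] = None
                        ) -> Optional[TrnaGeneRecord]:
    isotype_norm = _normalize_isotype(isotype)
    if isotype_norm is None:
        return None
    anticodon = anticodon.upper().replace("U", "T")
    if anticodon not in SENSE_ANTICODONS:
        return None
    strand = "+"
    if begin > end:  # tRNAscan-SE encodes minus strand as begin > end
        begin, end, strand = end, begin, "-"
    # Cross-check isotype against the anticodon's Watson-Crick codon; the
    # annotated isotype wins on mismatch (covers e.g. edge-case annotations).
    wc_aa = CODON_TO_AA.get(wc_codon(anticodon))
    if wc_aa is not None and AA3_TO_AA1.get(isotype_norm) != wc_aa:
        logger.warning(
            "isotype %s inconsistent with anticodon %s (WC codon encodes %s)",
            isotype_norm, anticodon, wc_aa)
    return TrnaGeneRecord(seq_id=seq_id, begin=begin, end=end, strand=strand,
                          isotype=isotype_norm, anticodon=anticodon,
                          score=score, intron=intron)


def read_trna_table(path, dialect: str = "trnascan_se") -> List[TrnaGeneRecord]:
    """Read a tRNA gene table.

    ``trnascan_se``: the legacy tabular output of tRNAscan-SE (three header
    lines, tab-separated columns: sequence name, tRNA number, begin, end,
    isotype, anticodon, intron begin, intron end, score, and optionally a
    note column).  Rows flagged as pseudogenes and rows with undetermined
    isotypes are dropped, with counts logged.

    ``simple_tsv``: a two-column header ``anticodon<TAB>count`` table,
    expanded to count-many synthetic records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "trnascan_se":
        return _read_trnascan(path)
    if dialect == "simple_tsv":
        return _read_simple_tsv(path)
    raise ValueError(f"unknown tRNA table dialect {dialect!r}")


def _read_trnascan(path: Path) -> List[TrnaGeneRecord]:
    records: List[TrnaGeneRecord] = []
    dropped_pseudo = dropped_und = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            first = line.split("\t")[0].strip()
            if first in ("Sequence", "Name") or set(first) <= {"-", " "}:
                continue  # header block
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 9:
                raise ValueError(
                    f"{path}:{lineno}: expected >=9 tab-separated fields, "
                    f"got {len(fields)}")
            try:
                begin, end = int(fields[2]), int(fields[3])
                intron_b, intron_e = int(fields[6]), int(fields[7])
                score = float(fields[8])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}")
            note = " ".join(fields[9:]).lower()
            if "pseudo" in note:
                dropped_pseudo += 1
                continue
            intron = None
            if intron_b and intron_e:
                lo, hi = sorted((intron_b, intron_e))
                intron = (lo, hi)
            rec = _record_from_fields(fields[0], begin, end, fields[4],
                                      fields[5], score, intron)
            if rec is None:
                dropped_und += 1
                continue
            records.append(rec)
    if dropped_pseudo or dropped_und:
        logger.info("read_trna_table: dropped %d pseudogene and %d "
                    "undetermined rows", dropped_pseudo, dropped_und)
    return records


def _read_simple_tsv(path: Path) -> List[TrnaGeneRecord]:
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "anticodon" not in cols or "count" not in cols:
        raise ValueError(
            f"{path}: simple_tsv requires columns 'anticodon' and 'count'")
    records: List[TrnaGeneRecord] = []
    pos = 1
    aa1_to_aa3 = {v: k for k, v in AA3_TO_AA1.items()}
    for _, row in df.iterrows():
        anticodon = str(row[cols["anticodon"]]).upper().replace("U", "T")
        count = int(row[cols["count"]])
        if count < 0:
            raise ValueError(f"negative count for anticodon {anticodon}")
        aa = CODON_TO_AA.get(wc_codon(anticodon))
        if aa is None:
            raise ValueError(f"{anticodon} is not a sense anticodon")
        for _i in range(count):
            records.append(TrnaGeneRecord(
                seq_id="synthetic", begin=pos, end=pos + 71, strand="+",
                isotype=aa1_to_aa3[aa], anticodon=anticodon, score=50.0))
            pos += 1000
    return records


def read_cds_fasta(path) -> Tuple[Dict[str, str], Dict[str, CdsQc]]:
    """Read CDS sequences, returning ``(sequences, qc_flags)`` keyed by id.

    Sequences are uppercased; alphabet {A,C,G,T,N}.  QC flags record length
    not divisible by 3, internal stop codons (in frame, before the last
    codon), and N content.  Duplicate ids are an error.
    """
    seqs: Dict[str, str] = {}
    qc: Dict[str, CdsQc] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(
                f"{rec.id}: non-ACGTN characters {sorted(bad)!r}")
        flags = CdsQc(n_count=seq.count("N"))
        if len(seq) % 3:
            flags.length_not_multiple_of_3 = True
        codons = [seq[i:i + 3] for i in range(0, len(seq) - 2, 3)]
        if any(c in STOP_CODONS for c in codons[:-1]):
            flags.internal_stop = True
        seqs[rec.id] = seq
        qc[rec.id] = flags
    return seqs, qc


def read_gff3(path) -> List[GeneModel]:
    """Read gene models from GFF3 (1-based inclusive coordinates kept)."""
    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True,
                            merge_strategy="create_unique")
    models: List[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.end < gene.start:
            raise ValueError(f"gene {gene.id}: end < start")
        biotype = gene.attributes.get(
            "biotype", gene.attributes.get("gene_biotype", ["protein_coding"])
        )[0]
        model = GeneModel(gene_id=gene.id, seq_id=gene.seqid,
                          strand=gene.strand, start=gene.start, end=gene.end,
                          biotype=biotype)
        for tx in db.children(gene, level=1):
            if tx.featuretype not in ("mRNA", "transcript"):
                continue
            exons = []
            for exon in db.children(tx, featuretype="exon"):
                if exon.end < exon.start:
                    raise ValueError(f"exon of {tx.id}: end < start")
                if not (gene.start <= exon.start and exon.end <= gene.end):
                    raise ValueError(
                        f"exon of {tx.id} outside gene span of {gene.id}")
                exons.append((exon.start, exon.end))
            model.transcripts[tx.id] = sorted(exons)
        models.append(model)
    return models


def read_expression_table(path) -> pd.DataFrame:
    """Read an expression TSV: transcript_id, gene_id, then numeric columns.

    Numeric columns are per-sample fragment counts or precomputed FPM (a
    column whose values sum to 1e6 within 1e-3 relative tolerance is taken
    as FPM as-is downstream; the reader only validates non-negativity).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "gene_id"}
    if not required <= set(df.columns):
        raise ValueError(f"expression table needs columns {sorted(required)}")
    value_cols = [c for c in df.columns if c not in required]
    if not value_cols:
        raise ValueError("expression table has no numeric sample columns")
    for c in value_cols:
        if (df[c] < 0).any():
            raise ValueError(f"negative values in expression column {c!r}")
    return df


def read_category_map(path) -> pd.DataFrame:
    """Read a gene->category TSV (gene_id, category_id[, category_name])."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "category_id"} <= set(df.columns):
        raise ValueError("category map needs gene_id and category_id columns")
    if "category_name" not in df.columns:
        df["category_name"] = df["category_id"]
    return df


def read_paa_table(path) -> Dict[str, float]:
    """Read a particulate-amino-acid table (amino_acid, concentration).

    Amino acids may be one- or three-letter codes; returns a dict keyed by
    one-letter code.  Concentrations must be non-negative.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "amino_acid" not in cols or "concentration" not in cols:
        raise ValueError("PAA table needs amino_acid and concentration")
    out: Dict[str, float] = {}
    for _, row in df.iterrows():
        aa = str(row[cols["amino_acid"]]).strip()
        if len(aa) == 3:
            aa = AA3_TO_AA1.get(aa.capitalize(), aa)
        aa = aa.upper()
        conc = float(row[cols["concentration"]])
        if conc < 0:
            raise ValueError(f"negative PAA concentration for {aa}")
        if aa in out:
            raise ValueError(f"duplicate amino acid {aa} in PAA table")
        out[aa] = conc
    return out


def write_results(table: pd.DataFrame, path,
                  columns: Optional[Sequence[str]] = None) -> None:
    """Write a result table as TSV with deterministic formatting.

    Column order is fixed (given order, else sorted with any 'gene'/'gene_id'
    column first) and floats are printed with 6 significant digits so that
    re-running on identical input is byte-identical.
    """
    df = table.copy()
    if columns is None:
        lead = [c for c in ("gene", "gene_id", "category_id") if c in df.columns]
        rest = sorted(c for c in df.columns if c not in lead)
        columns = lead + rest
    df = df[list(columns)]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g",
              lineterminator="\n")
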