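"""Seeded generator of self-consistent synthetic fixtures.

Emulates the statistical structure the analysis assumes, with recorded
ground truth: a genomic tRNA census (per-amino-acid totals and within-family
splits drawn from Dirichlet priors, with an optional list of absent
anticodons), CDS sets whose amino-acid choice follows T_i^gamma and whose
synonymous-codon choice follows TF_ij^beta, log-normal expression levels
rank-coupled to each gene's tRNA adaptation, a genome layout placing tRNA
loci in introns versus intergenic spans, and a particulate-amino-acid vector
with a target correlation to the per-amino-acid tRNA content.

Defaults mirror the sea cucumber study conditions: 1032 total tRNA gene
copies, about 4.7% of tRNA loci intronic, and an intron:intergenic span
ratio that plants a 1:2.9 density contrast.  All randomness flows through
per-stage substreams derived from (seed, stage name), so adding a stage
never perturbs earlier stages' draws and regeneration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .adaptation_indices import TaiWeights, tai, tai_weights
from .codon_usage import count_codons
from .genetic_code import (
    AA_TO_CODONS,
    AA1_TO_AA3,
    MISSING_ANTICODONS_AJAPONICUS,
    SENSE_ANTICODONS,
    wc_anticodon,
)
from .trna_inventory import (
    ANTICODON_TO_AA,
    TrnaCensus,
    isoacceptor_frequencies,
)

__all__ = [
    "SimulationConfig",
    "SyntheticBundle",
    "generate_census",
    "generate_genes",
    "generate_expression",
    "generate_layout",
    "generate_paa",
    "generate_categories",
    "write_bundle",
]

#: intergenic span planting a 1:2.9 intron:intergenic density contrast at the
#: study's intronic locus fraction (49 of 1032) and a 2 Mb intron span:
#: S_ig = S_in * (1 - f) / (2.9 * f)
_DEFAULT_INTRON_BP = 2_000_000
_DEFAULT_INTERGENIC_BP = int(round(
    _DEFAULT_INTRON_BP * (983 / 49) / 2.9))


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of one synthetic bundle."""

    seed: int = 0
    # genes
    n_genes: int = 200
    median_codons: float = 300.0
    length_sigma: float = 0.6
    min_codons: int = 50
    max_codons: int = 3000
    #: codon-adaptation exponent: synonymous codon drawn with prob ~ TF^beta
    beta: float = 1.0
    #: amino-acid-adaptation exponent: amino acid drawn with prob ~ T_i^gamma
    gamma: float = 1.0
    #: optional gene classes (label, n_genes, beta, gamma); overrides n_genes
    gene_classes: Optional[Tuple[Tuple[str, int, float, float], ...]] = None
    # census
    total_trna_copies: int = 1032
    family_alpha: float = 2.0
    within_family_alpha: float = 1.0
    missing_anticodons: Tuple[str, ...] = ()
    allow_empty_families: bool = False
    # expression
    expr_mu: float = 2.0
    expr_sigma: float = 1.5
    rho_expression: float = 0.3
    # layout
    n_protein_genes: int = 100
    exon_bp: int = 200
    trna_bp: int = 72
    intron_span_bp: int = _DEFAULT_INTRON_BP
    intergenic_span_bp: int = _DEFAULT_INTERGENIC_BP
    intronic_trna_fraction: float = 49 / 1032
    # ecology
    rho_paa: float = 0.7
    # categories
    n_categories: int = 20

    def __post_init__(self) -> None:
        if not -1 <= self.rho_expression <= 1:
            raise ValueError("rho_expression must lie in [-1, 1]")
        if not -1 <= self.rho_paa <= 1:
            raise ValueError("rho_paa must lie in [-1, 1]")
        if self.total_trna_copies < 20:
            raise ValueError("need at least 20 tRNA gene copies")
        bad = set(self.missing_anticodons) - SENSE_ANTICODONS
        if bad:
            raise ValueError(f"not sense anticodons: {sorted(bad)}")

    @classmethod
    def sea_cucumber(cls, seed: int = 0, n_genes: int = 200,
                   beta: float = 4.0, gamma: float = 1.0,
                   **overrides) -> "SimulationConfig":
        """The sea cucumber-like preset: 1032 tRNA copies with the genome's
        16 absent anticodons, strong codon adaptation (beta=4, gamma=1)."""
        return cls(seed=seed, n_genes=n_genes, beta=beta, gamma=gamma,
                   missing_anticodons=MISSING_ANTICODONS_AJAPONICUS,
                   total_trna_copies=1032, **overrides)

    def classes(self) -> Tuple[Tuple[str, int, float, float], ...]:
        if self.gene_classes is not None:
            return tuple(self.gene_classes)
        label = f"b{self.beta:g}".replace(".", "p").replace("-", "m")
        return ((label, self.n_genes, self.beta, self.gamma),)


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic substream for one generation stage."""
    return np.random.default_rng(
        [int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])


def generate_census(config: SimulationConfig,
                    rng: Optional[np.random.Generator] = None) -> TrnaCensus:
    """Draw genomic copy numbers per anticodon.

    Per-amino-acid totals follow a Dirichlet-multinomial over the 20 amino
    acids; each family's total is split among its non-missing anticodons by
    another Dirichlet-multinomial.  Every amino acid keeps at least one copy
    unless the missing list removes the entire family (an error unless
    ``allow_empty_families``).
    """
    rng = rng or _stage_rng(config.seed, "census")
    missing = set(config.missing_anticodons)
    aas = sorted(AA_TO_CODONS)

    allowed: Dict[str, List[str]] = {}
    for aa in aas:
        family = sorted(wc_anticodon(c) for c in AA_TO_CODONS[aa])
        allowed[aa] = [a for a in family if a not in missing]
        if not allowed[aa] and not config.allow_empty_families:
            raise ValueError(
                f"missing list removes every anticodon of {AA1_TO_AA3[aa]}")

    probs = rng.dirichlet([config.family_alpha] * len(aas))
    totals = rng.multinomial(config.total_trna_copies, probs)
    # keep every (feasible) family represented
    for i, aa in enumerate(aas):
        if totals[i] == 0 and allowed[aa]:
            j = int(np.argmax(totals))
            totals[j] -= 1
            totals[i] = 1

    t = {a: 0 for a in sorted(SENSE_ANTICODONS)}
    for i, aa in enumerate(aas):
        if not allowed[aa] or totals[i] == 0:
            continue
        split_probs = rng.dirichlet(
            [config.within_family_alpha] * len(allowed[aa]))
        split = rng.multinomial(int(totals[i]), split_probs)
        for a, n in zip(allowed[aa], split):
            t[a] = int(n)
    return TrnaCensus(t=t, species="synthetic")


def generate_genes(config: SimulationConfig, census: TrnaCensus,
                   rng: Optional[np.random.Generator] = None
                   ) -> Tuple[Dict[str, str], Dict[str, dict]]:
    """Draw CDS sequences whose usage tracks the census with exponents.

    Returns ``(sequences, truth)``: sequences are ATG + body + stop, truth
    records each gene's class label, beta, gamma and body codon count.
    Amino acids are drawn with probability proportional to T_i^gamma and
    synonymous codons within the family proportional to TF_ij^beta (beta=0
    is uniform within the family, including codons with no cognate tRNA).
    """
    rng = rng or _stage_rng(config.seed, "genes")
    tf = isoacceptor_frequencies(census)
    totals = census.totals_by_aa()
    aas = sorted(aa for aa in AA_TO_CODONS if totals.get(aa, 0) > 0)

    sequences: Dict[str, str] = {}
    truth: Dict[str, dict] = {}
    for label, n_genes, beta, gamma in config.classes():
        aa_w = np.array([totals[aa] ** gamma for aa in aas], dtype=float)
        aa_p = aa_w / aa_w.sum()
        codon_p: Dict[str, Tuple[List[str], np.ndarray]] = {}
        for aa in aas:
            codons = list(AA_TO_CODONS[aa])
            w = np.array(
                [tf.tf.get(wc_anticodon(c), 0.0) ** beta for c in codons])
            if w.sum() == 0:
                w = np.ones(len(codons))
            codon_p[aa] = (codons, w / w.sum())

        lengths = np.exp(rng.normal(np.log(config.median_codons),
                                    config.length_sigma, size=n_genes))
        lengths = np.clip(np.round(lengths), config.min_codons,
                          config.max_codons).astype(int)
        for i in range(n_genes):
            gene_id = f"g_{label}_{i + 1:04d}"
            L = int(lengths[i])
            aa_seq = np.asarray(rng.choice(aas, size=L, p=aa_p))
            codons = np.empty(L, dtype=object)
            for aa in np.unique(aa_seq):
                idx = np.where(aa_seq == aa)[0]
                cands, p = codon_p[str(aa)]
                picks = rng.choice(len(cands), size=len(idx), p=p)
                for j, pk in zip(idx, picks):
                    codons[j] = cands[pk]
            sequences[gene_id] = "ATG" + "".join(codons) + "TAA"
            truth[gene_id] = {"class": label, "beta": beta, "gamma": gamma,
                              "body_codons": L}
    return sequences, truth


def generate_expression(config: SimulationConfig,
                        adaptation: Mapping[str, float],
                        rng: Optional[np.random.Generator] = None
                        ) -> Dict[str, float]:
    """Log-normal per-gene fragment counts, rank-coupled to adaptation.

    A Gaussian copula couples the log-expression to the normal scores of the
    genes' adaptation values (tAI truth) with correlation ``rho_expression``;
    rho = 0 gives independent log-normal expression.
    """
    rng = rng or _stage_rng(config.seed, "expression")
    genes = sorted(adaptation)
    n = len(genes)
    vals = np.array([adaptation[g] for g in genes])
    # normal scores of adaptation ranks (ties broken by gene id order)
    order = np.argsort(vals, kind="stable")
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    z_adapt = stats.norm.ppf((ranks - 0.5) / n)
    rho = config.rho_expression
    z = rho * z_adapt + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
    fragments = np.exp(config.expr_mu + config.expr_sigma * z)
    return {g: float(f) for g, f in zip(genes, fragments)}


def generate_layout(config: SimulationConfig, census: TrnaCensus,
                    rng: Optional[np.random.Generator] = None
                    ) -> Tuple[str, str, Dict[str, int]]:
    """Place protein genes and tRNA loci on one synthetic chromosome.

    Returns ``(gff3_text, trna_table_text, seq_lengths)``.  Protein-coding
    genes are two-exon models whose introns together cover
    ``intron_span_bp``; the gaps between genes cover ``intergenic_span_bp``.
    Each tRNA locus (one per census copy) falls inside a random intron with
    probability ``intronic_trna_fraction``, else in a random intergenic gap.
    The tRNA table is written in the tRNAscan-SE legacy tabular dialect.
    """
    rng = rng or _stage_rng(config.seed, "layout")
    seq = "chr_syn"
    n_pg = config.n_protein_genes
    intron_len = config.intron_span_bp // n_pg
    gap_len = config.intergenic_span_bp // (n_pg + 1)

    gff_lines = ["##gff-version 3"]
    introns: List[Tuple[int, int]] = []
    gaps: List[Tuple[int, int]] = []
    pos = 1
    for i in range(n_pg):
        gaps.append((pos, pos + gap_len - 1))
        pos += gap_len
        g_start = pos
        e1 = (pos, pos + config.exon_bp - 1)
        intron = (e1[1] + 1, e1[1] + intron_len)
        e2 = (intron[1] + 1, intron[1] + config.exon_bp)
        g_end = e2[1]
        introns.append(intron)
        gid, tid = f"pg{i + 1:04d}", f"pg{i + 1:04d}.t1"
        gff_lines += [
            f"{seq}\tsynthetic\tgene\t{g_start}\t{g_end}\t.\t+\t.\t"
            f"ID={gid};biotype=protein_coding",
            f"{seq}\tsynthetic\tmRNA\t{g_start}\t{g_end}\t.\t+\t.\t"
            f"ID={tid};Parent={gid}",
            f"{seq}\tsynthetic\texon\t{e1[0]}\t{e1[1]}\t.\t+\t.\tParent={tid}",
            f"{seq}\tsynthetic\texon\t{e2[0]}\t{e2[1]}\t.\t+\t.\tParent={tid}",
        ]
        pos = g_end + 1
    gaps.append((pos, pos + gap_len - 1))
    pos += gap_len
    seq_lengths = {seq: pos - 1}

    # one locus per census copy, in deterministic anticodon order
    loci: List[Tuple[str, str, int, int]] = []
    for anticodon in sorted(census.t):
        for _copy in range(census.t[anticodon]):
            if rng.random() < config.intronic_trna_fraction:
                lo, hi = introns[rng.integers(len(introns))]
            else:
                lo, hi = gaps[rng.integers(len(gaps))]
            start = int(rng.integers(lo + 1, hi - config.trna_bp - 1))
            aa = ANTICODON_TO_AA[anticodon]
            loci.append((AA1_TO_AA3[aa], anticodon, start,
                         start + config.trna_bp - 1))

    header = ("Sequence\t\ttRNA\tBounds\ttRNA\tAnti\tIntron Bounds\tInf\n"
              "Name\ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\n"
              "--------\t------\t-----\t----\t----\t-----\t-----\t---\t-----\n")
    rows = [
        f"{seq}\t{i + 1}\t{start}\t{end}\t{aa3}\t{anticodon}\t0\t0\t50.0"
        for i, (aa3, anticodon, start, end) in enumerate(loci)
    ]
    return "\n".join(gff_lines) + "\n", header + "\n".join(rows) + "\n", seq_lengths


def generate_paa(config: SimulationConfig, census: TrnaCensus,
                 rng: Optional[np.random.Generator] = None
                 ) -> Dict[str, float]:
    """A particulate-amino-acid vector correlated with the tRNA totals.

    Models an acid-hydrolysed sample: 18 amino acids, with Asn pooled into
    Asp and Gln into Glu.  Concentrations are an affine transform of the
    merged tRNA totals plus Gaussian noise whose standard deviation is
    calibrated so the expected Pearson correlation is ``rho_paa``; a constant
    shift keeps all concentrations positive without clipping (so the target
    correlation is not attenuated).
    """
    rng = rng or _stage_rng(config.seed, "paa")
    totals = dict(census.totals_by_aa())
    totals["D"] = totals.get("D", 0) + totals.pop("N", 0)
    totals["E"] = totals.get("E", 0) + totals.pop("Q", 0)
    aas = sorted(totals)
    T = np.array([totals[aa] for aa in aas], dtype=float)

    rho = config.rho_paa
    if abs(rho) < 1e-12:
        conc = rng.random(len(aas)) * (T.std() + 1.0)
    else:
        sd_noise = T.std(ddof=0) * np.sqrt(max(1.0 / rho ** 2 - 1.0, 0.0))
        conc = np.sign(rho) * T + sd_noise * rng.standard_normal(len(aas))
    conc = conc - conc.min() + 0.01 * (conc.std() + 1.0)
    return {aa: float(c) for aa, c in zip(aas, conc)}


def generate_categories(config: SimulationConfig, genes: Sequence[str],
                        rng: Optional[np.random.Generator] = None
                        ) -> List[Tuple[str, str, str]]:
    """Random gene->category assignments (1-3 categories per gene)."""
    rng = rng or _stage_rng(config.seed, "categories")
    rows = []
    for g in sorted(genes):
        k = int(rng.integers(1, 4))
        cats = rng.choice(config.n_categories, size=k, replace=False)
        for c in sorted(int(x) for x in cats):
            cid = f"CAT{c + 1:03d}"
            rows.append((g, cid, f"category {c + 1}"))
    return rows


@dataclass(frozen=True)
class SyntheticBundle:
    """Paths and ground truth of one generated fixture set."""

    directory: Path
    trna_table: Path
    cds_fasta: Path
    gff3: Path
    expression: Path
    categories: Path
    paa: Path
    manifest: Path


def write_bundle(config: SimulationConfig, outdir) -> SyntheticBundle:
    """Generate and write a complete bundle; byte-identical per seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    census = generate_census(config)
    sequences, truth = generate_genes(config, census)

    # adaptation truth for the expression coupling
    weights: TaiWeights = tai_weights(census)
    adaptation = {g: tai(count_codons(s, g), weights) or 0.0
                  for g, s in sequences.items()}
    fragments = generate_expression(config, adaptation)
    gff3_text, trna_text, seq_lengths = generate_layout(config, census)
    paa = generate_paa(config, census)
    cat_rows = generate_categories(config, list(sequences))

    paths = SyntheticBundle(
        directory=outdir,
        trna_table=outdir / "trna.tsv",
        cds_fasta=outdir / "cds.fasta",
        gff3=outdir / "genome.gff3",
        expression=outdir / "expression.tsv",
        categories=outdir / "categories.tsv",
        paa=outdir / "paa.tsv",
        manifest=outdir / "manifest.json",
    )
    paths.trna_table.write_text(trna_text)
    paths.gff3.write_text(gff3_text)
    with open(paths.cds_fasta, "w") as fh:
        for g in sorted(sequences):
            fh.write(f">{g}\n{sequences[g]}\n")
    with open(paths.expression, "w") as fh:
        fh.write("transcript_id\tgene_id\tfragments\n")
        for g in sorted(fragments):
            fh.write(f"{g}.t1\t{g}\t{fragments[g]:.6f}\n")
    with open(paths.categories, "w") as fh:
        fh.write("gene_id\tcategory_id\tcategory_name\n")
        for g, cid, name in cat_rows:
            fh.write(f"{g}\t{cid}\t{name}\n")
    with open(paths.paa, "w") as fh:
        fh.write("amino_acid\tconcentration\n")
        for aa in sorted(paa):
            fh.write(f"{aa}\t{paa[aa]:.6f}\n")

    manifest = {
        "config": dataclasses.asdict(config),
        "seq_lengths": seq_lengths,
        "truth": {
            "census": {a: census.t[a] for a in sorted(census.t)},
            "genes": {g: truth[g] for g in sorted(truth)},
            "adaptation_tai": {g: round(adaptation[g], 10)
                               for g in sorted(adaptation)},
            "rho_paa": config.rho_paa,
        },
    }
    paths.manifest.write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return paths
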