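"""Per-gene co-adaptation indices between codon usage and the tRNA pool.

Three complementary indices:

* **CSI** — Pearson correlation between a gene's synonymous codon frequencies
  (CF) and the genomic isoacceptor tRNA frequencies (TF), pooled across
  amino-acid families.  It measures adaptation of synonymous-codon choice
  only; the family normalization removes all amino-acid composition signal.
* **TAAI** — Pearson correlation between a gene's amino-acid usage and the
  per-amino-acid tRNA gene copy numbers.  It measures adaptation of
  amino-acid composition only.
* **tAI** — geometric mean, over a gene's codons, of tRNA-availability
  weights derived from the census under extended decoding rules with
  pairing-type penalties.  It mixes both levels.  The species-specific
  variant tunes the wobble penalties by maximizing the rank correlation of
  tAI with an external objective (typically expression).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .codon_usage import (
    GeneCodonCounts,
    amino_acid_usage,
    synonymous_frequencies,
    transcriptome_codon_frequencies,
    weighted_aa_usage,
)
from .genetic_code import (
    AA_TO_CODONS,
    EXTENDED,
    EXTENDED_DECODING_PAIRS,
    WATSON_CRICK,
    PairingRule,
    SENSE_CODONS,
    allocate_codon_counts,
    wc_anticodon,
)
from .trna_inventory import (
    ANTICODON_TO_AA,
    IsoacceptorFrequencies,
    TrnaCensus,
)

__all__ = [
    "CorrelationResult",
    "TaiWeights",
    "DEFAULT_S_PENALTIES",
    "csi",
    "taai",
    "transcriptome_correlations",
    "tai_weights",
    "tai",
    "stai_optimize",
    "relative_rank",
    "build_profiles",
    "stratify",
]


@dataclass(frozen=True)
class CorrelationResult:
    """A Pearson correlation with its two-sided p-value and point count.

    ``defined`` is False when fewer than 3 points survive filtering or one
    axis has zero variance; r and p are then None rather than NaN.
    """

    r: Optional[float]
    p: Optional[float]
    n: int
    defined: bool = True

    @classmethod
    def undefined(cls, n: int = 0) -> "CorrelationResult":
        return cls(r=None, p=None, n=n, defined=False)


def _pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult.undefined(n)
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=n)


def csi(counts: GeneCodonCounts, tf: IsoacceptorFrequencies,
        rule: PairingRule = WATSON_CRICK,
        census: Optional[TrnaCensus] = None,
        include_single_codon_families: bool = False) -> CorrelationResult:
    """Coefficient of synonymous codon usage to isoaccepting tRNA frequency.

    Points are pooled across amino-acid families before a single Pearson
    correlation.  Under Watson–Crick rules each codon contributes a
    (TF of its cognate anticodon, CF) point.  Under extended rules the gene's
    codon counts are first allocated equally among the present anticodons
    that can decode them (orphan mass excluded from both axes), re-normalized
    within each family, and correlated against TF per anticodon.  Families
    with a single synonymous codon (Met, Trp) are excluded by default: their
    forced (1, 1) points carry no information and inflate r.

    The per-gene default is Watson-Crick pairing — the index as defined
    correlates synonymous codon frequencies with their cognate isoacceptor
    frequencies; the equal-allocation extended variant redistributes counts
    among wobble decoders and measures a different (coarser) quantity, so it
    is opt-in here and used chiefly at the transcriptome level.
    """
    xs: List[float] = []
    ys: List[float] = []
    if rule.mode == "watson_crick":
        cf = synonymous_frequencies(counts)
        aa_totals = counts.aa_counts()
        for aa, codons in AA_TO_CODONS.items():
            if len(codons) < 2 and not include_single_codon_families:
                continue
            if aa_totals.get(aa, 0) == 0 or aa in tf.undefined_aas:
                continue
            for codon in codons:
                xs.append(tf.tf[wc_anticodon(codon)])
                ys.append(cf[codon])
    else:
        if census is None:
            raise ValueError("extended-rule CSI needs the census to know "
                             "which anticodons are present")
        present = census.present_anticodons()
        alloc = allocate_codon_counts(counts.c, present, rule)
        by_aa: Dict[str, Dict[str, float]] = {}
        for a, mass in alloc.allocated.items():
            by_aa.setdefault(ANTICODON_TO_AA[a], {})[a] = mass
        for aa, masses in sorted(by_aa.items()):
            family = sorted(a for a in present if ANTICODON_TO_AA[a] == aa)
            if len(family) < 2 and not include_single_codon_families:
                continue
            total = sum(masses.values())
            if total <= 0 or aa in tf.undefined_aas:
                continue
            for a in family:
                xs.append(tf.tf[a])
                ys.append(masses.get(a, 0.0) / total)
    return _pearson(xs, ys)


def taai(aa_usage: Mapping[str, float], census: TrnaCensus) -> CorrelationResult:
    """tRNA gene copy number / amino-acid usage accordance index.

    Pearson correlation over the 20 amino acids between a gene's amino-acid
    counts and the genome's per-amino-acid tRNA copy totals.  Scale-invariant:
    counts and frequencies give identical r.
    """
    totals = census.totals_by_aa()
    aas = sorted(AA_TO_CODONS)
    x = [float(aa_usage.get(aa, 0)) for aa in aas]
    y = [float(totals.get(aa, 0)) for aa in aas]
    return _pearson(x, y)


def transcriptome_correlations(
        all_counts: Sequence[GeneCodonCounts],
        census: TrnaCensus,
        tf: IsoacceptorFrequencies,
        e: Optional[Mapping[str, float]] = None) -> Dict[str, object]:
    """Transcriptome-level co-adaptation summary.

    Computes the pooled TF-vs-TCF Pearson correlation under Watson–Crick and
    extended rules, per-amino-acid correlations (Watson–Crick), and the
    correlation between per-amino-acid tRNA totals and expression-weighted
    amino-acid usage.
    """
    usage = transcriptome_codon_frequencies(all_counts, e)

    # Watson-Crick: per-codon points, families with >=2 codons
    xs, ys = [], []
    per_aa: Dict[str, CorrelationResult] = {}
    for aa, codons in sorted(AA_TO_CODONS.items()):
        if len(codons) < 2 or aa in tf.undefined_aas:
            continue
        if not all(c in usage.tcf for c in codons):
            continue
        fx = [tf.tf[wc_anticodon(c)] for c in codons]
        fy = [usage.tcf[c] for c in codons]
        xs.extend(fx)
        ys.extend(fy)
        per_aa[aa] = _pearson(fx, fy)
    pooled_wc = _pearson(xs, ys)

    # Extended: weighted codon mass allocated among present anticodons
    present = census.present_anticodons()
    alloc = allocate_codon_counts(usage.w, present, EXTENDED)
    by_aa: Dict[str, Dict[str, float]] = {}
    for a, mass in alloc.allocated.items():
        by_aa.setdefault(ANTICODON_TO_AA[a], {})[a] = mass
    xs, ys = [], []
    for aa, masses in sorted(by_aa.items()):
        family = sorted(a for a in present if ANTICODON_TO_AA[a] == aa)
        if len(family) < 2 or aa in tf.undefined_aas:
            continue
        total = sum(masses.values())
        if total <= 0:
            continue
        for a in family:
            xs.append(tf.tf[a])
            ys.append(masses.get(a, 0.0) / total)
    pooled_ext = _pearson(xs, ys)

    waa = weighted_aa_usage(all_counts, e)
    aa_level = taai(waa, census)

    return {
        "pooled_wc": pooled_wc,
        "pooled_extended": pooled_ext,
        "per_aa_wc": per_aa,
        "aa_level": aa_level,
        "orphan_mass": alloc.orphan_mass,
    }


#: Classical wobble-pairing penalties used as tAI defaults and as the stAI
#: starting point: I:U is free (counted as Watson-Crick), G:U = 0.41,
#: I:C = 0.28, I:A = 0.9999, U:G = 0.68.
DEFAULT_S_PENALTIES: Dict[str, float] = {
    "wc": 0.0,
    "gu": 0.41,
    "ug": 0.68,
    "ic": 0.28,
    "ia": 0.9999,
}


@dataclass(frozen=True)
class TaiWeights:
    """Per-codon relative adaptiveness weights w_i in (0, 1]."""

    w: Mapping[str, float]
    s: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_S_PENALTIES))

    def __post_init__(self) -> None:
        vals = list(self.w.values())
        if not vals or not math.isclose(max(vals), 1.0, rel_tol=1e-9):
            raise ValueError("weights must be normalized to max 1")


def tai_weights(census: TrnaCensus,
                s: Optional[Mapping[str, float]] = None) -> TaiWeights:
    """Absolute adaptiveness W_i = sum over decoding anticodons of (1-s)*t.

    The sum runs over anticodons present in the census that decode codon i
    under extended rules, each discounted by the penalty of its pairing type
    (Watson–Crick pairs are never penalized).  Weights are normalized by the
    maximum; codons with W_i = 0 receive the geometric mean of the nonzero
    normalized weights — the standard missing-value convention, which keeps
    the geometric-mean aggregation finite.
    """
    s_map = dict(DEFAULT_S_PENALTIES)
    if s is not None:
        unknown = set(s) - set(s_map)
        if unknown:
            raise ValueError(f"unknown pairing types {sorted(unknown)}")
        s_map.update(s)
    if s_map["wc"] != 0.0:
        raise ValueError("the Watson-Crick penalty is fixed at 0")
    if any(not 0 <= v <= 1 for v in s_map.values()):
        raise ValueError("penalties must lie in [0, 1]")
    if census.total_copies == 0:
        raise ValueError("all-zero census")

    W: Dict[str, float] = {}
    for codon in sorted(SENSE_CODONS):
        W[codon] = sum((1.0 - s_map[ptype]) * census.t[a]
                       for a, ptype in EXTENDED_DECODING_PAIRS[codon])
    w_max = max(W.values())
    if w_max <= 0:
        raise ValueError("no codon has a nonzero weight")
    w = {c: v / w_max for c, v in W.items()}
    nonzero = [v for v in w.values() if v > 0]
    gm = math.exp(sum(math.log(v) for v in nonzero) / len(nonzero))
    w = {c: (v if v > 0 else gm) for c, v in w.items()}
    return TaiWeights(w=w, s=s_map)


def tai(counts: GeneCodonCounts, weights: TaiWeights) -> Optional[float]:
    """tRNA adaptation index: count-weighted geometric mean of codon weights.

    Returns None for a gene with no counted codons.
    """
    L = counts.L
    if L == 0:
        return None
    log_sum = sum(n * math.log(weights.w[codon])
                  for codon, n in counts.c.items())
    return math.exp(log_sum / L)


def stai_optimize(census: TrnaCensus,
                  gene_counts: Sequence[GeneCodonCounts],
                  objective: Mapping[str, float],
                  seed: int = 0,
                  grid_step: float = 0.05,
                  grid: Optional[Sequence[float]] = None,
                  max_rounds: int = 20) -> Tuple[TaiWeights, float]:
    """Species-specific tAI: tune wobble penalties against an objective.

    Deterministic coordinate ascent on the grid {0, grid_step, ..., 1} over
    the four wobble penalty classes (gu, ug, ic, ia), maximizing the Spearman
    correlation between per-gene tAI and ``objective`` (typically expression).
    The scan order of classes is fixed; ``seed`` selects the starting point
    among {classical defaults snapped to the grid, all-zero, all-one}.
    Returns the best weights and the achieved correlation.
    """
    genes = [g for g in gene_counts if g.L > 0]
    if len(genes) < 30:
        raise ValueError("stAI optimization needs at least 30 genes")
    obj = np.array([float(objective[g.gene_id]) for g in genes])
    if np.ptp(obj) == 0:
        raise ValueError("objective values are constant")

    if grid is None:
        grid = np.round(np.arange(0.0, 1.0 + 1e-9, grid_step), 10)
    else:
        grid = np.asarray(sorted(grid), dtype=float)
    classes = ("gu", "ug", "ic", "ia")
    starts = [
        {k: float(grid[np.argmin(np.abs(grid - DEFAULT_S_PENALTIES[k]))])
         for k in classes},
        {k: float(grid[0]) for k in classes},
        {k: float(grid[-1]) for k in classes},
    ]
    current = dict(starts[seed % len(starts)])

    def score(s_map: Dict[str, float]) -> float:
        weights = tai_weights(census, s_map)
        values = np.array([tai(g, weights) for g in genes])
        if np.ptp(values) == 0:
            return -2.0
        return float(stats.spearmanr(values, obj).statistic)

    best = score(current)
    for _ in range(max_rounds):
        improved = False
        for cls in classes:
            cand_scores = []
            for v in grid:
                trial = dict(current)
                trial[cls] = float(v)
                cand_scores.append((score(trial), -v))
            top, neg_v = max(cand_scores)
            v_best = -neg_v
            if top > best + 1e-12:
                current[cls] = v_best
                best = top
                improved = True
        if not improved:
            break
    return tai_weights(census, current), best


def relative_rank(values: Mapping[str, float]) -> Dict[str, float]:
    """Fractional percentile ranks in (0, 1], ties averaged.

    Undefined inputs (None/NaN) are excluded from the ranking and absent
    from the result.
    """
    items = [(g, v) for g, v in values.items()
             if v is not None and not (isinstance(v, float) and math.isnan(v))]
    if not items:
        return {}
    genes = [g for g, _ in items]
    ranks = stats.rankdata([v for _, v in items], method="average")
    n = len(items)
    return {g: float(r) / n for g, r in zip(genes, ranks)}


def build_profiles(all_counts: Sequence[GeneCodonCounts],
                   census: TrnaCensus,
                   tf: IsoacceptorFrequencies,
                   rule: PairingRule = WATSON_CRICK,
                   e: Optional[Mapping[str, float]] = None,
                   weights: Optional[TaiWeights] = None) -> pd.DataFrame:
    """Per-gene adaptation profile table.

    Columns: gene, L, mean_expr, csi, csi_p, csi_n, taai, taai_p, tai, and
    relative ranks rel_csi / rel_taai / rel_tai (percentiles among defined
    genes, ties averaged).  Undefined index values are NaN in the table.
    """
    if weights is None:
        weights = tai_weights(census)
    rows = []
    for gc in all_counts:
        c = csi(gc, tf, rule, census=census)
        t = taai(amino_acid_usage(gc), census)
        ti = tai(gc, weights)
        if e is None:
            expr = float("nan")
        else:
            val = e.get(gc.gene_id, float("nan"))
            expr = (float(np.mean(val))
                    if isinstance(val, Sequence) and not isinstance(val, str)
                    else float(val))
        rows.append({
            "gene": gc.gene_id,
            "L": gc.L,
            "mean_expr": expr,
            "csi": c.r if c.defined else float("nan"),
            "csi_p": c.p if c.defined else float("nan"),
            "csi_n": c.n,
            "taai": t.r if t.defined else float("nan"),
            "taai_p": t.p if t.defined else float("nan"),
            "tai": ti if ti is not None else float("nan"),
        })
    df = pd.DataFrame(rows)
    for col in ("csi", "taai", "tai"):
        defined = df[col].notna()
        ranks = relative_rank(
            dict(zip(df.loc[defined, "gene"], df.loc[defined, col])))
        df[f"rel_{col}"] = df["gene"].map(ranks)
    return df


def stratify(profiles: pd.DataFrame, by: str = "length",
             fraction: float = 0.05, n_bins: int = 10,
             all_counts: Optional[Sequence[GeneCodonCounts]] = None,
             census: Optional[TrnaCensus] = None,
             tf: Optional[IsoacceptorFrequencies] = None) -> pd.DataFrame:
    """Stratum summaries of the adaptation indices.

    ``by='expression'`` contrasts the top and bottom ``fraction`` of genes by
    mean expression; ``by='length'`` splits genes into ``n_bins`` quantile
    bins of codon count.  Each stratum reports its size and the median, IQR
    and standard deviation of csi / taai / tai.  When ``all_counts``,
    ``census`` and ``tf`` are given, each stratum additionally reports the
    pooled TF-vs-TCF Pearson r computed from the stratum's genes alone
    (unweighted).  Strata with fewer than 3 genes are flagged.
    """
    if by == "expression":
        ranked = profiles.dropna(subset=["mean_expr"]).sort_values(
            ["mean_expr", "gene"])
        k = max(int(len(ranked) * fraction), 1)
        strata = {"bottom": ranked.head(k), "top": ranked.tail(k)}
    elif by == "length":
        df = profiles.copy()
        df["_bin"] = pd.qcut(df["L"].rank(method="first"), n_bins,
                             labels=False)
        strata = {f"L_decile_{int(b) + 1}": grp
                  for b, grp in df.groupby("_bin")}
    else:
        raise ValueError(f"unknown stratification {by!r}")

    counts_by_gene = ({gc.gene_id: gc for gc in all_counts}
                      if all_counts is not None else None)

    rows = []
    for name, grp in strata.items():
        row: Dict[str, object] = {"stratum": name, "n": len(grp),
                                  "too_small": len(grp) < 3}
        if counts_by_gene is not None and census is not None and tf is not None:
            subset = [counts_by_gene[g] for g in grp["gene"]
                      if g in counts_by_gene]
            pooled = transcriptome_correlations(subset, census, tf)
            res = pooled["pooled_wc"]
            row["pooled_r"] = res.r if res.defined else float("nan")
        for col in ("csi", "taai", "tai"):
            vals = grp[col].dropna()
            row[f"{col}_median"] = float(vals.median()) if len(vals) else float("nan")
            row[f"{col}_iqr"] = (float(vals.quantile(0.75) - vals.quantile(0.25))
                                 if len(vals) else float("nan"))
            row[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
        row["median_L"] = float(grp["L"].median())
        rows.append(row)
    return pd.DataFrame(rows)
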