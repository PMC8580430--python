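"""Downstream statistics on adaptation profiles.

Top/bottom-tail category enrichment (hypergeometric with BH FDR), pathway
index contrasts (Wilcoxon rank-sum), per-category mean relative index, and
the ecological correlation between genomic tRNA content and the amino-acid
composition of particulate organic matter (the sea cucumber's food).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .adaptation_indices import CorrelationResult, _pearson
from .trna_inventory import TrnaCensus

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "select_extremes",
    "enrich",
    "pathway_contrast",
    "category_profile",
    "paa_correlation",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One category's over-representation in a gene selection."""

    category_id: str
    category_name: str
    count: int  # selected genes in the category
    category_size: int  # background genes in the category
    p: float  # one-sided hypergeometric upper tail
    fold: float  # (count/selection) / (category/background)
    fdr: float  # Benjamini-Hochberg adjusted


def select_extremes(profiles: pd.DataFrame, index: str = "taai",
                    fraction: float = 0.1) -> Tuple[Set[str], Set[str]]:
    """Top and bottom tails of the gene set by an adaptation index.

    Selection is by value with ties at the boundary broken by gene id
    (lexicographic), so it is deterministic.  Genes with an undefined index
    are excluded (count logged).  Tail size is floor(n * fraction).
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must lie in (0, 0.5]")
    if index not in profiles.columns:
        raise ValueError(f"no column {index!r} in profiles")
    defined = profiles.dropna(subset=[index])
    n_undef = len(profiles) - len(defined)
    if n_undef:
        logger.info("select_extremes: %d genes with undefined %s excluded",
                    n_undef, index)
    ordered = defined.sort_values([index, "gene"])
    k = int(len(ordered) * fraction)
    bottom = set(ordered.head(k)["gene"])
    top = set(ordered.tail(k)["gene"])
    return top, bottom


def enrich(selection: Set[str], categories: pd.DataFrame,
           background: Set[str], min_selected: int = 2,
           ease: bool = False) -> List[EnrichmentResult]:
    """Category over-representation in a gene selection.

    One-sided hypergeometric upper-tail p per category (population =
    ``background``, successes = background genes in the category, draws =
    ``selection``), BH FDR across the tested categories.  Categories with
    fewer than ``min_selected`` selected genes are skipped.  ``ease=True``
    applies the EASE correction (one success removed from the overlap),
    the conservative variant used by DAVID.
    """
    if not background:
        raise ValueError("empty background")
    if not selection <= background:
        raise ValueError("selection must be a subset of the background")
    N, n = len(background), len(selection)

    by_cat: Dict[str, Tuple[str, Set[str]]] = {}
    for _, row in categories.iterrows():
        if row["gene_id"] not in background:
            continue
        cid = str(row["category_id"])
        by_cat.setdefault(cid, (str(row["category_name"]), set()))
        by_cat[cid][1].add(row["gene_id"])

    tested: List[Tuple[str, str, int, int, float, float]] = []
    for cid in sorted(by_cat):
        name, members = by_cat[cid]
        K = len(members)
        k = len(members & selection)
        if k < min_selected:
            continue
        k_eff = max(k - 1, 0) if ease else k
        p = float(stats.hypergeom.sf(k_eff - 1, N, K, n))
        fold = (k / n) / (K / N)
        tested.append((cid, name, k, K, p, fold))

    if not tested:
        return []
    _, fdrs, _, _ = multipletests([t[4] for t in tested], method="fdr_bh")
    return [
        EnrichmentResult(category_id=cid, category_name=name, count=k,
                         category_size=K, p=p, fold=fold, fdr=float(q))
        for (cid, name, k, K, p, fold), q in zip(tested, fdrs)
    ]


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """Exact rank-sum p by enumeration of all group assignments."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    w_obs = float(ranks[:n1].sum())
    ws = [float(sum(combo))
          for combo in itertools.combinations(ranks, n1)]
    ws = np.array(ws)
    if alternative == "greater":
        return float(np.mean(ws >= w_obs - 1e-9))
    if alternative == "less":
        return float(np.mean(ws <= w_obs + 1e-9))
    mean_w = ws.mean()
    dev = abs(w_obs - mean_w)
    return float(np.mean(np.abs(ws - mean_w) >= dev - 1e-9))


def pathway_contrast(pathway_genes: Iterable[str], profiles: pd.DataFrame,
                     index: str = "taai", alternative: str = "two-sided",
                     method: str = "normal") -> Tuple[float, float]:
    """Wilcoxon rank-sum contrast of a pathway against all remaining genes.

    Returns ``(W, p)`` where W is the rank-sum of the pathway group.
    ``method='normal'`` uses the normal approximation with tie correction and
    no continuity correction; ``method='exact'`` enumerates all group
    assignments (small groups only).  ``alternative`` may be 'two-sided',
    'greater' (pathway higher) or 'less'.
    """
    pathway_genes = set(pathway_genes)
    defined = profiles.dropna(subset=[index])
    x = defined.loc[defined["gene"].isin(pathway_genes), index].to_numpy()
    y = defined.loc[~defined["gene"].isin(pathway_genes), index].to_numpy()
    if len(x) < 3:
        raise ValueError("pathway must have >= 3 genes with a defined index")
    if len(y) == 0:
        raise ValueError("empty complement")
    ranks = stats.rankdata(np.concatenate([x, y]))
    w = float(ranks[: len(x)].sum())
    if method == "exact":
        if math.comb(len(x) + len(y), len(x)) > 200_000:
            raise ValueError("groups too large for exact enumeration")
        return w, _exact_ranksum_p(x, y, alternative)
    if method != "normal":
        raise ValueError(f"unknown method {method!r}")
    res = stats.mannwhitneyu(x, y, alternative=alternative,
                             method="asymptotic", use_continuity=False)
    return w, float(res.pvalue)


def category_profile(categories: pd.DataFrame,
                     rel_index: Mapping[str, float]) -> pd.DataFrame:
    """Mean relative index per category (empty categories skipped)."""
    rows = []
    for (cid, name), grp in categories.groupby(
            ["category_id", "category_name"], sort=True):
        vals = [rel_index[g] for g in grp["gene_id"] if g in rel_index]
        if not vals:
            continue
        rows.append({"category_id": cid, "category_name": name,
                     "mean_rel_index": float(np.mean(vals)),
                     "n_genes": len(vals)})
    return pd.DataFrame(rows)


#: Acid hydrolysis of particulate protein deamidates Asn to Asp and Gln to
#: Glu, so PAA tables usually report Asx/Glx pools under Asp/Glu labels.
_HYDROLYSIS_MERGE = {"N": "D", "Q": "E"}


def paa_correlation(census: TrnaCensus, paa: Mapping[str, float],
                    merge_hydrolysis: Optional[bool] = None
                    ) -> CorrelationResult:
    """Pearson correlation between tRNA copy totals and food amino acids.

    Pairs per-amino-acid genomic tRNA copy numbers T_i with the particulate
    amino-acid concentrations, matched by amino-acid identity; only amino
    acids present in both vectors are used (n reported).  When the PAA table
    has 18 or fewer amino acids (the acid-hydrolysis signature),
    tRNA totals for Asn/Gln are merged into Asp/Glu by default
    (``merge_hydrolysis`` overrides the auto-detection).
    """
    totals = dict(census.totals_by_aa())
    if merge_hydrolysis is None:
        merge_hydrolysis = len(paa) <= 18
    if merge_hydrolysis:
        for src, dst in _HYDROLYSIS_MERGE.items():
            if src not in paa:
                totals[dst] = totals.get(dst, 0) + totals.pop(src, 0)
    shared = sorted(set(totals) & set(paa))
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} amino acids shared between census and PAA")
    x = [float(totals[aa]) for aa in shared]
    y = [float(paa[aa]) for aa in shared]
    return _pearson(x, y)
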