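"""CSI, TAAI, tAI and ranking against independent oracles."""

import math

import numpy as np
import pytest

from trnacoadapt.adaptation_indices import (
    DEFAULT_S_PENALTIES,
    TaiWeights,
    build_profiles,
    csi,
    relative_rank,
    stai_optimize,
    stratify,
    taai,
    tai,
    tai_weights,
    transcriptome_correlations,
)
from trnacoadapt.codon_usage import GeneCodonCounts, count_codons
from trnacoadapt.genetic_code import EXTENDED, WATSON_CRICK
from trnacoadapt.synthetic_data import (
    SimulationConfig,
    generate_census,
    generate_genes,
)
from trnacoadapt.trna_inventory import isoacceptor_frequencies

from conftest import make_census


def pearson_oracle(x, y):
    """Textbook Pearson r, written independently of scipy."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def test_csi_is_one_for_perfectly_matched_usage():
    census = make_census({"GTC": 3, "ATC": 1, "GCC": 1, "TCC": 3})
    tf = isoacceptor_frequencies(census)
    gene = GeneCodonCounts("g", c={"GAC": 30, "GAT": 10,   # Asp CF = TF
                                   "GGC": 10, "GGA": 30})  # Gly CF = TF
    res = csi(gene, tf, WATSON_CRICK)
    assert res.defined and res.r == pytest.approx(1.0)


def test_csi_matches_pearson_oracle_on_toy_points():
    # two 2-codon families: TF (0.75, 0.25) and (0.6, 0.4);
    # gene usage CF (0.7, 0.3) and (0.5, 0.5)
    census = make_census({"GTC": 3, "ATC": 1, "GCA": 3, "ACA": 2})
    tf = isoacceptor_frequencies(census)
    gene = GeneCodonCounts("g", c={"GAC": 7, "GAT": 3, "TGC": 5, "TGT": 5})
    res = csi(gene, tf, WATSON_CRICK)
    expected = pearson_oracle([0.75, 0.25, 0.6, 0.4], [0.7, 0.3, 0.5, 0.5])
    assert res.r == pytest.approx(expected, abs=1e-12)
    assert res.n == 4


def test_csi_reversed_ranking_is_negative():
    census = make_census({"GTC": 3, "ATC": 1, "GCA": 3, "ACA": 1})
    tf = isoacceptor_frequencies(census)
    gene = GeneCodonCounts("g", c={"GAC": 1, "GAT": 3, "TGC": 1, "TGT": 3})
    res = csi(gene, tf, WATSON_CRICK)
    assert res.defined and res.r < 0


def test_csi_undefined_when_too_few_points():
    census = make_census({"GTC": 3, "ATC": 1})
    tf = isoacceptor_frequencies(census)
    gene = GeneCodonCounts("g", c={"GAC": 5, "GAT": 5})
    res = csi(gene, tf, WATSON_CRICK)
    assert not res.defined and res.r is None and res.n == 2


def test_csi_extended_excludes_orphan_mass():
    # Val codons are orphans when only CAC is present and counts use GTT
    census = make_census({"CAC": 2, "GTC": 2, "ATC": 2, "GCC": 1, "TCC": 3})
    tf = isoacceptor_frequencies(census)
    gene = GeneCodonCounts("g", c={"GTT": 50, "GAC": 3, "GAT": 1,
                                   "GGC": 1, "GGA": 3})
    res = csi(gene, tf, EXTENDED, census=census)
    assert res.defined  # orphan Val mass dropped, Asp+Gly points remain
    assert res.n == 4


def test_taai_examples_and_oracle():
    census = make_census({"GTC": 20, "GCC": 10, "GCA": 6, "GTG": 4})
    # usage proportional to T -> r = 1
    usage = {"D": 10, "G": 5, "C": 3, "H": 2}
    res = taai(usage, census)
    assert res.defined and res.r == pytest.approx(1.0)
    # against the oracle on the full 20-vector, anti-ordered tRNA totals
    census2 = make_census({"GTC": 4, "GCC": 6, "GCA": 10, "GTG": 20})
    res2 = taai(usage, census2)
    aas = sorted("ACDEFGHIKLMNPQRSTVWY")
    x = [usage.get(aa, 0) for aa in aas]
    t2 = census2.totals_by_aa()
    y = [t2.get(aa, 0) for aa in aas]
    assert res2.r == pytest.approx(pearson_oracle(x, y), abs=1e-12)


def test_taai_undefined_for_uniform_census():
    # one copy of one anticodon per amino acid: every family total is 1,
    # so the tRNA axis has zero variance
    from trnacoadapt.genetic_code import AA_TO_CODONS, wc_anticodon
    copies = {wc_anticodon(codons[0]): 1 for codons in AA_TO_CODONS.values()}
    census = make_census(copies)
    res = taai({"D": 5, "G": 1}, census)
    assert not res.defined


def test_taai_scale_invariance():
    census = make_census({"GTC": 20, "GCC": 10, "GCA": 6, "GTG": 4})
    usage = {"D": 10, "G": 4, "C": 5, "H": 1}
    scaled = {aa: 11.0 * v for aa, v in usage.items()}
    assert taai(usage, census).r == pytest.approx(taai(scaled, census).r,
                                                  abs=1e-12)


def test_pearson_ops_match_oracle_on_random_fixtures(rng):
    for _ in range(200):
        n = rng.integers(3, 25)
        x = rng.random(n)
        y = rng.random(n) + 0.2 * x
        from trnacoadapt.adaptation_indices import _pearson
        res = _pearson(x, y)
        assert res.r == pytest.approx(pearson_oracle(list(x), list(y)),
                                      abs=1e-12)


def test_tai_weight_construction_and_missing_value_convention():
    census = make_census({"GTC": 4, "GCC": 2})
    weights = tai_weights(census)
    assert max(weights.w.values()) == 1.0
    # GAC is decoded Watson-Crick by the most abundant anticodon
    assert weights.w["GAC"] == 1.0
    # GAT picks up GTC through G:U wobble at penalty 0.41
    assert weights.w["GAT"] == pytest.approx((1 - 0.41) * 4 / 4)
    # codons with no decoder get the geometric mean of nonzero weights
    nonzero = [v for c, v in weights.w.items()
               if c not in ("TTT",) and v > 0]
    assert weights.w["TTT"] > 0


def test_tai_examples():
    w = TaiWeights(w={"GAC": 1.0, "GAT": 0.25, "GGA": 0.5, "TGC": 0.2})
    assert tai(GeneCodonCounts("g", c={"GAC": 7}), w) == 1.0
    assert tai(GeneCodonCounts("g", c={"GAC": 3, "GAT": 3}), w) == \
        pytest.approx(0.5)
    val = tai(GeneCodonCounts("g", c={"GAC": 2, "GGA": 1, "TGC": 1}), w)
    assert val == pytest.approx((1.0 ** 2 * 0.5 * 0.2) ** 0.25)
    assert tai(GeneCodonCounts("g", c={}), w) is None


def test_tai_bounds_and_maximality():
    census = make_census({"GTC": 4, "ATC": 1, "GCC": 2})
    weights = tai_weights(census)
    rng = np.random.default_rng(3)
    codons = sorted(weights.w)
    for _ in range(50):
        picks = rng.choice(codons, size=20)
        gc = GeneCodonCounts("g", c={})
        for c in picks:
            gc.c[c] = gc.c.get(c, 0) + 1
        v = tai(gc, weights)
        assert 0 < v <= 1
        only_max = all(weights.w[c] == 1.0 for c in gc.c)
        assert (v == pytest.approx(1.0)) == only_max


def test_tai_invariant_under_census_scaling():
    base = {"GTC": 4, "ATC": 1, "GCC": 2, "AAG": 5}
    w1 = tai_weights(make_census(base))
    w2 = tai_weights(make_census({a: 3 * v for a, v in base.items()}))
    for c in w1.w:
        assert w1.w[c] == pytest.approx(w2.w[c], abs=1e-12)


def test_relative_rank_examples():
    assert relative_rank({"a": 0.1, "b": 0.2, "c": 0.3}) == pytest.approx(
        {"a": 1 / 3, "b": 2 / 3, "c": 1.0})
    ranks = relative_rank({"a": 5.0, "b": 5.0, "c": 5.0})
    assert all(v == pytest.approx(2 / 3) for v in ranks.values())
    assert relative_rank({"only": 1.23}) == {"only": 1.0}
    assert relative_rank({"a": 1.0, "b": float("nan")}) == {"a": 1.0}


def _uniform_usage_genes(census, n_genes, seed, codons_per_gene=200):
    """Genes with codon usage uniform within families (maximal spread)."""
    config = SimulationConfig(seed=seed, n_genes=n_genes, beta=0.0,
                              gamma=0.0, median_codons=codons_per_gene,
                              length_sigma=0.0)
    seqs, _ = generate_genes(config, census)
    return [count_codons(s, g) for g, s in sorted(seqs.items())]


def test_stai_single_point_grid_returns_the_planted_penalties():
    census = generate_census(SimulationConfig(seed=5))
    genes = _uniform_usage_genes(census, 40, seed=5)
    s_star = {"gu": 0.3, "ug": 0.55, "ic": 0.45, "ia": 1.0}
    objective = {g.gene_id: tai(g, tai_weights(census, s_star))
                 for g in genes}
    weights, rho = stai_optimize(
        census, genes, objective,
        grid=sorted({0.3, 0.55, 0.45, 1.0}))
    # every class's optimum is in the grid; with the planted objective the
    # exact s* is recovered and the correlation is perfect
    assert rho == pytest.approx(1.0)
    for cls, v in s_star.items():
        if cls == "ia":
            continue  # negligible decoding mass; any value fits
        assert weights.s[cls] == pytest.approx(v)


def test_stai_null_objective_gives_near_zero_correlation():
    census = generate_census(SimulationConfig(seed=5))
    genes = _uniform_usage_genes(census, 60, seed=5, codons_per_gene=150)
    rng = np.random.default_rng(13)
    objective = {g.gene_id: float(v)
                 for g, v in zip(genes, rng.permutation(len(genes)))}
    _, rho = stai_optimize(census, genes, objective)
    assert abs(rho) < 0.3  # optimizer can only overfit the grid this much


def test_stai_requires_enough_genes_and_varying_objective():
    census = generate_census(SimulationConfig(seed=5))
    genes = _uniform_usage_genes(census, 40, seed=5)
    with pytest.raises(ValueError, match="constant"):
        stai_optimize(census, genes, {g.gene_id: 1.0 for g in genes})
    with pytest.raises(ValueError, match="at least 30"):
        stai_optimize(census, genes[:10],
                      {g.gene_id: float(i) for i, g in enumerate(genes[:10])})


def test_transcriptome_correlations_consistency_limit():
    """Codon usage sampled proportional to TF gives pooled r near 1."""
    config = SimulationConfig(seed=9, n_genes=60, beta=1.0, gamma=1.0,
                              median_codons=400, length_sigma=0.0)
    census = generate_census(config)
    tf = isoacceptor_frequencies(census)
    seqs, _ = generate_genes(config, census)
    counts = [count_codons(s, g) for g, s in sorted(seqs.items())]
    summary = transcriptome_correlations(counts, census, tf)
    assert summary["pooled_wc"].r > 0.95
    assert summary["aa_level"].defined


def test_extended_rule_raises_pooled_r_when_orphans_carry_mass():
    """With absent anticodons, wobble/ADAT reallocation explains codon mass
    that Watson-Crick pairing leaves uncorrelated (zero-TF codons)."""
    # Gly and Thr usage match the present isoacceptors exactly; Asp and Cys
    # put half their mass on codons whose cognate anticodons are absent.
    census = make_census({"GCC": 3, "TCC": 1,   # Gly (CCC, ACC absent)
                          "AGT": 2, "CGT": 2,   # Thr (GGT, TGT absent)
                          "GTC": 4,             # Asp (ATC absent)
                          "GCA": 2})            # Cys (ACA absent)
    tf = isoacceptor_frequencies(census)
    counts = [GeneCodonCounts("g", c={"GGC": 30, "GGA": 10,
                                      "ACT": 10, "ACG": 10,
                                      "GAC": 10, "GAT": 10,
                                      "TGC": 5, "TGT": 5})]
    summary = transcriptome_correlations(counts, census, tf)
    # Watson-Crick leaves (TF=0, TCF>0) mismatch points for Asp/Cys/...
    assert summary["pooled_wc"].r < 1.0
    # ... which extended decoding reassigns to their wobble/ADAT readers
    assert summary["pooled_extended"].r == pytest.approx(1.0)
    assert summary["pooled_extended"].r >= summary["pooled_wc"].r


def test_profiles_and_stratification(sea_cucumber_bundle):
    config, bundle = sea_cucumber_bundle
    from trnacoadapt.io_formats import read_cds_fasta, read_trna_table
    from trnacoadapt.trna_inventory import build_census
    records = read_trna_table(bundle.trna_table)
    census = build_census(records)
    tf = isoacceptor_frequencies(census)
    seqs, _ = read_cds_fasta(bundle.cds_fasta)
    counts = [count_codons(s, g) for g, s in sorted(seqs.items())]
    profiles = build_profiles(counts, census, tf)
    assert len(profiles) == len(seqs)
    assert profiles["csi"].between(-1, 1).all()
    assert profiles["tai"].between(0, 1).all()
    # percentile ranks of defined values are a permutation of i/n
    ranks = sorted(profiles["rel_tai"].dropna())
    n = len(ranks)
    assert ranks == pytest.approx([(i + 1) / n for i in range(n)])

    strata = stratify(profiles, by="length", n_bins=5,
                      all_counts=counts, census=census, tf=tf)
    assert len(strata) == 5
    assert not strata["too_small"].any()
    assert strata["pooled_r"].notna().all()


def test_identical_genes_give_identical_strata():
    gene = "ATG" + "GACGGA" * 50 + "TAA"
    counts = [count_codons(gene, f"g{i}") for i in range(20)]
    census = make_census({"GTC": 3, "ATC": 1, "GCC": 1, "TCC": 3})
    tf = isoacceptor_frequencies(census)
    profiles = build_profiles(counts, census, tf)
    strata = stratify(profiles, by="length", n_bins=2)
    assert strata["taai_median"].nunique() == 1
    assert strata["tai_median"].nunique() == 1
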