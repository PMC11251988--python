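import itertools

import numpy as np
import pytest
import scipy.stats

from srtmsi import (
    PipelineConfig,
    filter_genes,
    filter_spots,
    normalize_logcpm,
    pseudobulk_correlation,
    rank_markers,
    select_hvgs,
)
from srtmsi.srt import _ranksum_pvalues

from conftest import make_section


def boundary_fixture():
    """Six spots straddling both QC thresholds.

    Unique-gene counts {10, 50, 49, 200, 200, 200}; mito count fractions
    {0, 0, 0, 0.38, 0.39, 0.10}. Exactly the 50-gene spot and the two
    spots at or below 38% mito should survive.
    """
    rng = np.random.default_rng(7)
    n_genes = 250
    gene_ids = [f"g{i}" for i in range(n_genes - 1)] + ["mt-1"]
    counts = np.zeros((n_genes, 6), dtype=int)
    for spot, n_unique in enumerate([10, 50, 49, 200, 200, 200]):
        # 31 counts/gene makes the 0.38 = 19/31 mito fraction exactly realizable
        counts[rng.choice(n_genes - 1, n_unique, replace=False), spot] = 31
    for spot, frac in enumerate([0.0, 0.0, 0.0, 0.38, 0.39, 0.10]):
        non_mito = counts[:-1, spot].sum()
        counts[-1, spot] = int(round(non_mito * frac / (1 - frac)))
    return make_section(counts, gene_ids=gene_ids)


def test_filter_spots_boundary_thresholds(cfg):
    section = boundary_fixture()
    # check the fixture realizes the intended mito fractions
    mito_frac = section.counts[-1] / section.counts.sum(axis=0)
    np.testing.assert_allclose(mito_frac[3:], [0.38, 0.39, 0.10], atol=5e-4)

    kept, log = filter_spots(section, cfg)
    assert list(kept.barcodes) == ["bc1", "bc3", "bc5"]
    assert log.n_retained == 3
    assert log.n_low_genes == 2      # 10-gene and 49-gene spots
    assert log.n_high_mito == 1      # the 0.39 spot


def test_filter_spots_is_idempotent(cfg):
    once, _ = filter_spots(boundary_fixture(), cfg)
    twice, log = filter_spots(once, cfg)
    assert list(twice.barcodes) == list(once.barcodes)
    assert log.n_retained == once.n_spots


def test_filter_spots_excluding_everything_errors(cfg):
    section = boundary_fixture()
    with pytest.raises(ValueError, match="all spots removed"):
        filter_spots(section, cfg, exclude_barcodes=set(section.barcodes))


def test_filter_spots_drops_off_tissue(cfg):
    section = boundary_fixture()
    section.in_tissue[1] = False
    kept, _ = filter_spots(section, cfg)
    assert list(kept.barcodes) == ["bc3", "bc5"]


@pytest.mark.parametrize(
    "species,genes,expected",
    [
        ("mouse", ["Hba-a1", "Rps4x", "Malat1", "Th"], ["Th"]),
        ("human", ["ACTB"], ["ACTB"]),
        ("human", ["RPL13", "HBB", "MALAT1"], []),
        ("mouse", ["Hbb-bs", "Rpl3", "malat1", "Gapdh", "Hbegf"], ["Gapdh", "Hbegf"]),
    ],
)
def test_filter_genes_patterns(species, genes, expected):
    counts = np.ones((len(genes), 4), dtype=int)
    kept, n_removed = filter_genes(make_section(counts, gene_ids=genes), species)
    assert list(kept.gene_ids) == expected
    assert n_removed == len(genes) - len(expected)


def test_normalize_logcpm_closed_form():
    section = make_section([[1], [0]])
    normed = normalize_logcpm(section)
    np.testing.assert_allclose(normed[:, 0], [np.log(1 + 10000), 0.0])


def test_normalize_logcpm_scale_invariance(tiny_section):
    doubled = make_section(tiny_section.counts * 2)
    np.testing.assert_allclose(
        normalize_logcpm(tiny_section), normalize_logcpm(doubled), rtol=1e-12
    )


def test_normalize_logcpm_zero_spot_names_barcode():
    counts = np.array([[1, 0], [2, 0]])
    with pytest.raises(ValueError, match="bc1"):
        normalize_logcpm(make_section(counts))


def test_select_hvgs_finds_high_variance_gene():
    rng = np.random.default_rng(1)
    base = rng.normal(5.0, 0.3, size=(10, 400)).clip(min=0)
    base[4] = rng.normal(5.0, 3.0, size=400).clip(min=0)  # 100x the variance
    gene_ids = np.array([f"g{i}" for i in range(10)], dtype=object)
    assert select_hvgs(base, gene_ids, 1) == ["g4"]


def test_select_hvgs_never_picks_constant_genes():
    rng = np.random.default_rng(2)
    x = rng.normal(2.0, 1.0, size=(6, 100)).clip(min=0)
    x[2] = 3.0  # constant
    x[5] = 0.0
    gene_ids = np.array([f"g{i}" for i in range(6)], dtype=object)
    picked = select_hvgs(x, gene_ids, 4)
    assert "g2" not in picked and "g5" not in picked


def test_select_hvgs_n_equals_gene_count_returns_all():
    rng = np.random.default_rng(3)
    x = rng.normal(2.0, 1.0, size=(5, 50)).clip(min=0)
    gene_ids = np.array([f"g{i}" for i in range(5)], dtype=object)
    assert sorted(select_hvgs(x, gene_ids, 5)) == [f"g{i}" for i in range(5)]
    with pytest.raises(ValueError):
        select_hvgs(x, gene_ids, 6)


def _marker_fixture():
    rng = np.random.default_rng(0)
    normed = rng.normal(1.0, 0.5, size=(20, 40)).clip(min=0)
    labels = np.array(["A"] * 20 + ["B"] * 20)
    normed[0, :20] = 5.0
    normed[0, 20:] = 0.0
    return normed, labels


def test_rank_markers_flags_clean_marker(cfg):
    normed, labels = _marker_fixture()
    gene_ids = np.array([f"g{i}" for i in range(20)], dtype=object)
    table = rank_markers(normed, gene_ids, labels, cfg)
    row = table[(table.cluster == "A") & (table.gene == "g0")].iloc[0]
    assert row.significant and row.log2fc > 0.25 and row.padj < 0.01
    # identical-distribution genes are not significant
    other = table[(table.cluster == "A") & (table.gene != "g0")]
    assert not other.significant.any()


def test_rank_markers_bonferroni_and_flag_are_exact(cfg):
    normed, labels = _marker_fixture()
    gene_ids = np.array([f"g{i}" for i in range(20)], dtype=object)
    table = rank_markers(normed, gene_ids, labels, cfg)
    m = 20 * 2
    np.testing.assert_allclose(table.padj, np.minimum(table.pval * m, 1.0), rtol=1e-12)
    np.testing.assert_array_equal(
        table.significant, (table.log2fc > cfg.log2fc_min) & (table.padj < cfg.padj_max)
    )
    assert (table.padj >= table.pval - 1e-15).all()


def test_rank_markers_requires_three_spots_per_cluster(cfg):
    normed = np.ones((5, 10))
    labels = np.array(["A"] * 8 + ["B"] * 2)
    with pytest.raises(ValueError, match="fewer than 3"):
        rank_markers(normed, np.array([f"g{i}" for i in range(5)], dtype=object), labels, cfg)


def exhaustive_permutation_p(values, n1):
    """Exact two-sided rank-sum permutation p over all group-1 subsets."""
    ranks = scipy.stats.rankdata(values)
    total = len(values)
    observed = abs(ranks[:n1].sum() - n1 * (total + 1) / 2)
    hits = count = 0
    for combo in itertools.combinations(range(total), n1):
        count += 1
        stat = abs(ranks[list(combo)].sum() - n1 * (total + 1) / 2)
        if stat >= observed - 1e-9:
            hits += 1
    return hits / count


@pytest.mark.parametrize("shift", [0.0, 0.8, 2.0])
def test_wilcoxon_matches_exhaustive_permutation(shift):
    """Normal-approximation p agrees with the exact 924-split permutation
    null within 0.02 on 6-vs-6 toys, including under ties."""
    rng = np.random.default_rng(int(shift * 10) + 5)
    for _ in range(5):
        x = np.round(rng.normal(size=12), 1)  # rounding induces ties
        x[:6] += shift
        p_normal = _ranksum_pvalues(x[None, :], np.arange(12) < 6)[0]
        p_exact = exhaustive_permutation_p(x, 6)
        assert abs(p_normal - p_exact) < 0.02


def test_pseudobulk_self_correlation_is_one(default_synthetic):
    _, srt, _, _ = default_synthetic
    r = pseudobulk_correlation([srt, srt])
    np.testing.assert_allclose(r.to_numpy(), np.ones((2, 2)), atol=1e-12)


def test_pseudobulk_replicates_highly_concordant():
    from srtmsi import SynthConfig, generate_srt

    scfg = SynthConfig(seed=11)
    a = generate_srt(scfg)
    b = generate_srt(scfg, noise_seed=999)  # same means, independent NB noise
    r = pseudobulk_correlation([a, b])
    assert r.iloc[0, 1] >= 0.99
    values = r.to_numpy()
    np.testing.assert_allclose(values, values.T)
    assert np.linalg.eigvalsh(values).min() > -1e-10
    assert np.allclose(np.diag(values), 1.0)


def test_pseudobulk_alignment_by_gene_id(default_synthetic):
    _, srt, _, _ = default_synthetic
    rng = np.random.default_rng(0)
    perm = rng.permutation(srt.n_genes)
    shuffled = srt.subset_genes(perm)
    r1 = pseudobulk_correlation([srt, srt])
    r2 = pseudobulk_correlation([srt, shuffled])
    np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-12)


def test_pseudobulk_too_few_shared_genes_errors():
    a = make_section(np.ones((5, 3), int), gene_ids=[f"a{i}" for i in range(5)])
    b = make_section(np.ones((5, 3), int), gene_ids=[f"b{i}" for i in range(5)])
    with pytest.raises(ValueError, match="shared genes"):
        pseudobulk_correlation([a, b])
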