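"""Spot/gene QC, normalization, HVG selection, and marker ranking for SRT data.

QC rules follow the published workflow: spots with fewer than 50 unique
genes or more than 38% mitochondrial counts are removed, and hemoglobin-,
ribosomal-protein-coding and Malat1 genes are dropped before downstream
analysis. Normalization is log-CPM (counts scaled per spot to 10,000, then
log1p) — a monotone per-spot normalization standing in for heavier
variance-stabilizing transforms, which downstream correlation and embedding
steps do not require.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .config import PipelineConfig
from .datatypes import SRTSection

MARKER_TABLE_COLUMNS = ["cluster", "gene", "log2fc", "pval", "padj", "significant"]

_GENE_REMOVAL_PATTERNS = {
    "mouse": re.compile(r"^(Hb[ab]|Rp[sl]|Malat1)", re.IGNORECASE),
    "human": re.compile(r"^(HB[AB]|RP[SL]|MALAT1)", re.IGNORECASE),
}


@dataclass
class SpotFilterLog:
    n_input: int
    n_retained: int
    n_low_genes: int
    n_high_mito: int
    n_excluded_barcode: int
    n_not_in_tissue: int


def mito_mask(gene_ids: np.ndarray) -> np.ndarray:
    """Mitochondrial genes, detected by case-insensitive symbol prefix 'mt-'."""
    return np.array([str(g).lower().startswith("mt-") for g in gene_ids])


def filter_spots(
    section: SRTSection,
    cfg: PipelineConfig,
    exclude_barcodes: set[str] | None = None,
) -> tuple[SRTSection, SpotFilterLog]:
    """Remove low-quality spots.

    A spot is retained iff it detects at least ``cfg.min_genes_per_spot``
    unique genes, its mitochondrial count fraction is at most
    ``cfg.max_mito_frac``, it lies in tissue, and its barcode is not
    explicitly excluded. Thresholds are boundary-inclusive on the retained
    side: exactly 50 genes passes, exactly 0.38 mito fraction passes.
    """
    if section.n_spots == 0:
        raise ValueError("section has no spots")
    exclude_barcodes = exclude_barcodes or set()

    unique_genes = (section.counts > 0).sum(axis=0)
    totals = section.counts.sum(axis=0)
    mito = section.counts[mito_mask(section.gene_ids)].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)

    ok_genes = unique_genes >= cfg.min_genes_per_spot
    ok_mito = mito_frac <= cfg.max_mito_frac
    ok_barcode = np.array([b not in exclude_barcodes for b in section.barcodes])
    keep = ok_genes & ok_mito & ok_barcode & section.in_tissue

    log = SpotFilterLog(
        n_input=section.n_spots,
        n_retained=int(keep.sum()),
        n_low_genes=int((~ok_genes).sum()),
        n_high_mito=int((~ok_mito).sum()),
        n_excluded_barcode=int((~ok_barcode).sum()),
        n_not_in_tissue=int((~section.in_tissue).sum()),
    )
    if log.n_retained == 0:
        raise ValueError(
            "all spots removed by QC "
            f"(low genes: {log.n_low_genes}, high mito: {log.n_high_mito}, "
            f"excluded: {log.n_excluded_barcode}, off tissue: {log.n_not_in_tissue})"
        )
    return section.subset_spots(np.flatnonzero(keep)), log


def filter_genes(section: SRTSection, species: str = "mouse") -> tuple[SRTSection, int]:
    """Drop hemoglobin-coding, ribosomal-protein-coding and Malat1 genes.

    Returns the filtered section and the number of genes removed.
    """
    if species not in _GENE_REMOVAL_PATTERNS:
        raise ValueError(f"species must be mouse|human, got {species!r}")
    pattern = _GENE_REMOVAL_PATTERNS[species]
    drop = np.array([bool(pattern.match(str(g))) for g in section.gene_ids])
    return section.subset_genes(np.flatnonzero(~drop)), int(drop.sum())


def normalize_logcpm(section: SRTSection, target_sum: float = 1e4) -> np.ndarray:
    """Per-spot library-size normalization to ``target_sum`` followed by log1p."""
    totals = section.counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"all-zero spot(s): {list(section.barcodes[zero[:5]])}")
    return np.log1p(section.counts * (target_sum / totals))


def select_hvgs(normed: np.ndarray, gene_ids: np.ndarray, n: int) -> list[str]:
    """Top-n highly variable genes by variance standardized against a trend.

    The mean-variance trend is a degree-2 polynomial fit of log10 variance on
    log10 mean over all expressed genes; each gene's score is its variance
    divided by the trend's prediction at its mean. Deterministic; ties broken
    lexicographically by gene id. Constant genes are never selected while
    non-constant genes remain.
    """
    if n > normed.shape[0]:
        raise ValueError(f"requested {n} HVGs from {normed.shape[0]} genes")
    mean = normed.mean(axis=1)
    var = normed.var(axis=1, ddof=1) if normed.shape[1] > 1 else np.zeros(len(mean))
    usable = (var > 0) & (mean > 0)
    score = np.zeros(len(mean))
    log_mean = np.log10(mean[usable]) if usable.any() else np.array([])
    # a trend is only identifiable when means actually spread out; at a
    # (near-)common mean, raw variance is the standardized variance
    if usable.sum() >= 3 and np.ptp(log_mean) > 0.1:
        coef = np.polyfit(log_mean, np.log10(var[usable]), deg=2)
        trend = 10 ** np.polyval(coef, log_mean)
        score[usable] = var[usable] / trend
    else:
        score[usable] = var[usable]
    order = sorted(range(len(mean)), key=lambda i: (-score[i], str(gene_ids[i])))
    return [str(gene_ids[i]) for i in order[:n]]


def _ranksum_pvalues(normed: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p per gene, in-group vs rest.

    For small samples (up to 14 observations total) the exact tie-aware
    permutation null of the rank sum is enumerated; beyond that the normal
    approximation with tie correction and continuity correction is used,
    vectorized over genes.
    """
    n1 = int(in_group.sum())
    n2 = normed.shape[1] - n1
    ranks = scipy.stats.rankdata(normed, axis=1)
    if n1 + n2 <= 14:
        import itertools

        combos = np.array(list(itertools.combinations(range(n1 + n2), n1)))
        mu = n1 * (n1 + n2 + 1) / 2.0
        obs = np.abs(ranks[:, in_group].sum(axis=1) - mu)
        null_sums = ranks[:, combos].sum(axis=2)  # genes x combos
        return (np.abs(null_sums - mu) >= obs[:, None] - 1e-9).mean(axis=1)
    rank_sum = ranks[:, in_group].sum(axis=1)
    mu = n1 * (n1 + n2 + 1) / 2.0
    # tie correction per gene
    n = n1 + n2
    tie_term = np.zeros(normed.shape[0])
    for i in range(normed.shape[0]):
        _, counts = np.unique(normed[i], return_counts=True)
        tie_term[i] = (counts ** 3 - counts).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 0.0))
    diff = rank_sum - mu
    z = np.zeros_like(sigma)
    nz = sigma > 0
    z[nz] = (np.abs(diff[nz]) - 0.5) / sigma[nz]  # continuity correction
    z = np.maximum(z, 0.0)
    return np.minimum(2 * scipy.stats.norm.sf(z), 1.0)


def rank_markers(
    normed: np.ndarray,
    gene_ids: np.ndarray,
    labels: np.ndarray,
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker ranking with Bonferroni correction.

    For each cluster and gene: two-sided rank-sum test of in-cluster vs all
    other spots; log2 fold change of de-logged means with a 1e-9 pseudocount;
    Bonferroni over genes x clusters. A marker is significant iff its log2
    fold change exceeds ``cfg.log2fc_min`` and its adjusted P is below
    ``cfg.padj_max`` (strict inequalities).
    """
    labels = np.asarray(labels)
    clusters = sorted(set(labels))
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    for c in clusters:
        if (labels == c).sum() < 3:
            raise ValueError(f"cluster {c!r} has fewer than 3 spots")

    m = normed.shape[0] * len(clusters)
    expr = np.expm1(normed)
    rows = []
    for c in clusters:
        in_group = labels == c
        pvals = _ranksum_pvalues(normed, in_group)
        mean_in = expr[:, in_group].mean(axis=1)
        mean_out = expr[:, ~in_group].mean(axis=1)
        log2fc = np.log2((mean_in + 1e-9) / (mean_out + 1e-9))
        padj = np.minimum(pvals * m, 1.0)
        for i in range(normed.shape[0]):
            rows.append(
                (
                    c, str(gene_ids[i]), float(log2fc[i]), float(pvals[i]), float(padj[i]),
                    bool(log2fc[i] > cfg.log2fc_min and padj[i] < cfg.padj_max),
                )
            )
    table = pd.DataFrame(rows, columns=MARKER_TABLE_COLUMNS)
    return table.sort_values(
        ["cluster", "log2fc"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)


def pseudobulk_correlation(sections: list[SRTSection], min_shared: int = 100) -> pd.DataFrame:
    """Section-to-section Pearson correlation of log10 pseudobulk profiles.

    Per section, each shared gene's pseudobulk is log10(1 + summed counts);
    the result is the symmetric correlation matrix across sections, aligned
    by gene id (gene order within sections is irrelevant).
    """
    if len(sections) < 2:
        raise ValueError("need at least 2 sections")
    shared = set(sections[0].gene_ids)
    for s in sections[1:]:
        shared &= set(s.gene_ids)
    shared = sorted(shared)
    if len(shared) < min_shared:
        raise ValueError(f"only {len(shared)} shared genes (< {min_shared})")

    profiles = []
    for s in sections:
        index = {g: i for i, g in enumerate(s.gene_ids)}
        totals = s.counts.sum(axis=1)
        profiles.append(np.log10(1 + totals[[index[g] for g in shared]]))
    r = np.corrcoef(np.array(profiles))
    labels = [f"section_{i}" for i in range(len(sections))]
    return pd.DataFrame(r, index=labels, columns=labels)
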