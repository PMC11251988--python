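"""Metabolite-to-gene correlation screening with FDR control.

For a chosen m/z peak, the peak's per-observation intensity is correlated
(Pearson) with every retained gene's normalized expression across the paired
observations; two-sided P values come from the exact t transform, and the
Benjamini-Hochberg step-up procedure controls the FDR over the gene list.
Paired spots are treated as independent observations, as in the published
analysis; spatial autocorrelation is deliberately not corrected for (see the
methods note).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .datatypes import MultimodalDataset

CORR_TABLE_COLUMNS = ["peak_mz", "gene", "r", "pval", "qval", "significant"]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values (q values), input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        bad = p[(p < 0) | (p > 1)][0]
        raise ValueError(f"p-values must lie in [0, 1]; got {bad}")
    return multipletests(p, method="fdr_bh")[1]


def _pearson_columns(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided t-test p of vector ``y`` against each row of
    ``x``; constant rows get r=0, p=1 by convention."""
    n = len(y)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum())
    ok = (sx > 0) & (sy > 0)
    r = np.zeros(x.shape[0])
    r[ok] = (xc[ok] @ yc) / (sx[ok] * sy)
    r = np.clip(r, -1.0, 1.0)
    p = np.ones(x.shape[0])
    with np.errstate(divide="ignore"):
        t = r[ok] * np.sqrt((n - 2) / np.maximum(1 - r[ok] ** 2, 1e-300))
    p[ok] = 2 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    p = np.minimum(p, 1.0)
    return r, p


def peak_gene_correlation(
    mm: MultimodalDataset,
    peak_mz: float,
    cfg: PipelineConfig,
    log1p_peak: bool = False,
    mz_tol: float = 1e-3,
) -> pd.DataFrame:
    """Correlate one peak's intensity with every gene across paired spots.

    Returns one row per gene with columns peak_mz, gene, r, pval, qval,
    significant (qval < cfg.fdr_threshold), sorted by descending r. Constant
    genes are kept with r=0, p=1. Gene values are the log-normalized
    expression; the peak is used raw unless ``log1p_peak``.
    """
    if mm.n_obs < 10:
        raise ValueError(f"need at least 10 paired observations, got {mm.n_obs}")
    delta = np.abs(mm.mz - peak_mz)
    j = int(np.argmin(delta))
    if delta[j] > mz_tol:
        nearest = np.sort(mm.mz[np.argsort(delta)[:3]])
        raise ValueError(
            f"no peak within {mz_tol} Da of m/z {peak_mz}; nearest: "
            + ", ".join(f"{v:.4f}" for v in nearest)
        )
    peak = mm.peak_intensities[j].astype(float)
    if log1p_peak:
        peak = np.log1p(peak)
    if peak.std() == 0:
        raise ValueError(f"peak m/z {mm.mz[j]:.4f} is constant across observations")

    r, p = _pearson_columns(mm.gene_norm, peak)
    q = bh_adjust(p)
    table = pd.DataFrame(
        {
            "peak_mz": mm.mz[j],
            "gene": [str(g) for g in mm.gene_ids],
            "r": r,
            "pval": p,
            "qval": q,
            "significant": q < cfg.fdr_threshold,
        }
    )
    return table.sort_values("r", ascending=False, kind="stable").reset_index(drop=True)


def top_correlated_genes(
    table: pd.DataFrame, n: int, direction: str = "positive"
) -> list[str]:
    """The n significant genes with largest (positive) or smallest (negative) r."""
    if len(table) == 0:
        raise ValueError("empty correlation table")
    if direction not in ("positive", "negative"):
        raise ValueError(f"direction must be positive|negative, got {direction!r}")
    sig = table[table["significant"]]
    sig = sig.sort_values("r", ascending=(direction == "negative"), kind="stable")
    return sig["gene"].head(n).tolist()
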