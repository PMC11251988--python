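"""Mean-spectrum concordance and PCA-based off-tissue pixel removal.

Replicate concordance between consecutive sections is summarized as the
Pearson correlation of log10(1 + mean intensity) spectra. Off-tissue pixels
are detected from the first principal component of the log-transformed pixel
profiles: the PC1 scores are split into two clusters and the cluster with
the lower mean total intensity is flagged as background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import MSIRaster


@dataclass
class MeanSpectrum:
    mz: np.ndarray
    mean_intensity: np.ndarray
    n_pixels: int

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=float)
        if len(self.mz) != len(self.mean_intensity):
            raise ValueError("mz and mean_intensity lengths differ")
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")


def mean_spectrum(
    raster: MSIRaster,
    tissue_only: bool = False,
    offtissue: np.ndarray | None = None,
) -> MeanSpectrum:
    """Arithmetic mean intensity per peak over the selected pixels.

    With ``tissue_only``, an off-tissue flag vector (from
    :func:`flag_offtissue`) must be supplied and flagged pixels are excluded.
    """
    if raster.n_pixels == 0:
        raise ValueError("raster has no pixels")
    if tissue_only:
        if offtissue is None:
            raise ValueError("tissue_only requires an off-tissue flag vector")
        keep = ~np.asarray(offtissue, dtype=bool)
        if not keep.any():
            raise ValueError("no tissue pixels selected")
        selected = raster.intensities[:, keep]
    else:
        selected = raster.intensities
    return MeanSpectrum(
        mz=raster.mz,
        mean_intensity=selected.mean(axis=1),
        n_pixels=selected.shape[1],
    )


def spectrum_correlation(a: MeanSpectrum, b: MeanSpectrum, mz_tol: float = 1e-4) -> float:
    """Pearson r between two mean spectra on log10(1 + intensity) scale."""
    if len(a.mz) != len(b.mz):
        raise ValueError(f"spectra have {len(a.mz)} vs {len(b.mz)} peaks")
    mismatch = np.flatnonzero(np.abs(a.mz - b.mz) > mz_tol)
    if mismatch.size:
        i = mismatch[0]
        raise ValueError(
            f"m/z axes differ at peak {i}: {a.mz[i]:.4f} vs {b.mz[i]:.4f}"
        )
    x = np.log10(1 + a.mean_intensity)
    y = np.log10(1 + b.mean_intensity)
    return float(np.corrcoef(x, y)[0, 1])


def _two_means_split_1d(scores: np.ndarray) -> np.ndarray:
    """Exact 2-means on a 1-D array: the split of the sorted values that
    minimizes total within-class sum of squares. Returns a boolean mask of
    the upper cluster. Deterministic and order invariant."""
    order = np.argsort(scores, kind="stable")
    s = scores[order]
    n = len(s)
    csum = np.cumsum(s)
    csq = np.cumsum(s ** 2)
    best_cost, best_k = np.inf, 1
    for k in range(1, n):  # lower cluster = s[:k]
        lo = csq[k - 1] - csum[k - 1] ** 2 / k
        hi = (csq[-1] - csq[k - 1]) - (csum[-1] - csum[k - 1]) ** 2 / (n - k)
        cost = lo + hi
        if cost < best_cost - 1e-12:
            best_cost, best_k = cost, k
    upper = np.zeros(n, dtype=bool)
    upper[order[best_k:]] = True
    return upper


def flag_offtissue(
    raster: MSIRaster,
    manual_threshold: float | None = None,
    tic_normalize: bool = False,
) -> np.ndarray:
    """Flag background pixels via PCA of log-transformed pixel profiles.

    Pixel spectra are log10(1+x) transformed (optionally TIC-normalized
    first), centered, and projected on the first principal component. The
    PC1 scores are split by an exact two-cluster 1-D k-means, and the cluster
    with the lower mean total intensity is flagged off-tissue. With
    ``manual_threshold``, pixels whose total raw intensity falls below the
    threshold are flagged instead.

    Returns a boolean array, True = off-tissue.
    """
    if raster.n_pixels < 10:
        raise ValueError("need at least 10 pixels")
    if raster.n_peaks < 2:
        raise ValueError("need at least 2 peaks")

    totals = raster.intensities.sum(axis=0)
    if manual_threshold is not None:
        return totals < manual_threshold

    profiles = raster.intensities
    if tic_normalize:
        profiles = profiles / np.maximum(totals, 1e-12)
    x = np.log10(1 + profiles).T  # pixels x peaks
    x = x - x.mean(axis=0)
    if not x.any():
        warnings.warn("all pixels identical; flagging none as off-tissue", stacklevel=2)
        return np.zeros(raster.n_pixels, dtype=bool)
    # first right-singular direction = PC1; deterministic sign is irrelevant
    # because cluster identity is decided by total intensity, not score sign
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    scores = x @ vt[0]
    upper = _two_means_split_1d(scores)
    if totals[upper].mean() < totals[~upper].mean():
        off = upper
    else:
        off = ~upper
    return off
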