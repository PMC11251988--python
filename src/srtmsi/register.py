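"""Landmark registration of MSI pixels into the spot frame, and pairing.

Sections are rigid at the 100-um scale, so the MSI-to-common-frame mapping
is a similarity transform (rotation, isotropic scale, translation) fitted to
landmark point pairs by the closed-form least-squares (Umeyama/Procrustes)
solution. Pairing then proceeds exactly in the order of the published
procedure: k nearest spots per MSI pixel, a hard distance cutoff, then the
single closest surviving spot per pixel; a spot that is the closest neighbor
of several pixels is reused for each of them. The distance cutoff is
interpreted in the same frame as the supplied spot pixel coordinates
(full-resolution H&E pixels for standard Visium positions files).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import PipelineConfig
from .datatypes import MSIRaster, MultimodalDataset, SRTSection


@dataclass
class LandmarkPairs:
    source_xy: np.ndarray  # MSI-native units
    target_xy: np.ndarray  # common-frame pixels

    def __post_init__(self) -> None:
        self.source_xy = np.atleast_2d(np.asarray(self.source_xy, dtype=float))
        self.target_xy = np.atleast_2d(np.asarray(self.target_xy, dtype=float))
        if self.source_xy.shape != self.target_xy.shape:
            raise ValueError("source and target landmark lists differ in shape")
        if len(self.source_xy) < 2:
            raise ValueError("need at least 2 landmark pairs")
        if len(set(map(tuple, self.source_xy))) != len(self.source_xy):
            raise ValueError("duplicated source landmark points")

    @classmethod
    def from_csv(cls, path: str) -> "LandmarkPairs":
        table = pd.read_csv(path)
        required = ["source_x", "source_y", "target_x", "target_y"]
        missing = [c for c in required if c not in table.columns]
        if missing:
            raise ValueError(f"landmark CSV lacks columns {missing}")
        return cls(
            source_xy=table[["source_x", "source_y"]].to_numpy(float),
            target_xy=table[["target_x", "target_y"]].to_numpy(float),
        )

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            {
                "source_x": self.source_xy[:, 0],
                "source_y": self.source_xy[:, 1],
                "target_x": self.target_xy[:, 0],
                "target_y": self.target_xy[:, 1],
            }
        ).to_csv(path, index=False)


@dataclass
class SimilarityTransform2D:
    """p -> scale * R(rotation) * p + translation, optionally with reflection."""

    scale: float = 1.0
    rotation_rad: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    reflect: bool = False

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation_rad), np.sin(self.rotation_rad)
        rot = np.array([[c, -s], [s, c]])
        if self.reflect:
            rot = rot @ np.array([[1.0, 0.0], [0.0, -1.0]])
        return self.scale * rot

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return xy @ self.matrix.T + np.asarray(self.translation)

    def inverse(self) -> "SimilarityTransform2D":
        inv_matrix = np.linalg.inv(self.matrix)
        inv_t = -inv_matrix @ np.asarray(self.translation)
        inv_scale = float(np.sqrt(np.abs(np.linalg.det(inv_matrix))))
        bare = inv_matrix / inv_scale
        reflect = np.linalg.det(bare) < 0
        if reflect:
            bare = bare @ np.array([[1.0, 0.0], [0.0, -1.0]])
        return SimilarityTransform2D(
            scale=inv_scale,
            rotation_rad=float(np.arctan2(bare[1, 0], bare[0, 0])),
            translation=(float(inv_t[0]), float(inv_t[1])),
            reflect=bool(reflect),
        )


def fit_similarity(
    landmarks: LandmarkPairs, allow_reflection: bool = False
) -> SimilarityTransform2D:
    """Least-squares similarity transform from landmark pairs.

    Closed-form orthogonal-Procrustes-with-scale (Umeyama) solution
    minimizing sum ||T(source) - target||^2. With ``allow_reflection=False``
    the rotation determinant is constrained to +1.
    """
    src = landmarks.source_xy
    dst = landmarks.target_xy
    if np.allclose(src, src[0]):
        raise ValueError("degenerate configuration: all source landmarks coincide")

    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    xs, xd = src - mu_s, dst - mu_d
    cov = xd.T @ xs / len(src)
    u, d, vt = np.linalg.svd(cov)
    s_fix = np.eye(2)
    det_uv = np.linalg.det(u) * np.linalg.det(vt)
    if det_uv < 0:
        if allow_reflection:
            pass  # keep the reflecting optimum
        else:
            s_fix[1, 1] = -1.0
    rot = u @ s_fix @ vt
    var_s = (xs ** 2).sum() / len(src)
    if var_s == 0:
        raise ValueError("degenerate configuration: zero source variance")
    scale = float(np.trace(np.diag(d) @ s_fix) / var_s)
    if scale <= 0:
        raise ValueError("degenerate configuration: non-positive fitted scale")
    translation = mu_d - scale * rot @ mu_s

    reflect = np.linalg.det(rot) < 0
    bare = rot @ np.array([[1.0, 0.0], [0.0, -1.0]]) if reflect else rot
    return SimilarityTransform2D(
        scale=scale,
        rotation_rad=float(np.arctan2(bare[1, 0], bare[0, 0])),
        translation=(float(translation[0]), float(translation[1])),
        reflect=bool(reflect),
    )


def apply_transform(t: SimilarityTransform2D, raster: MSIRaster) -> np.ndarray:
    """Map a raster's pixel coordinates into the common frame."""
    return t.apply(raster.pixel_xy)


@dataclass
class PairMap:
    """Per-MSI-pixel assignment to its single nearest RNA spot.

    ``msi_pixel_index`` entries are unique; ``spot_index`` entries may repeat
    (several pixels sharing one closest spot reuse it).
    """

    msi_pixel_index: np.ndarray
    spot_index: np.ndarray
    distance_px: np.ndarray
    unpaired_msi_pixels: np.ndarray
    max_dist_px: float

    def __post_init__(self) -> None:
        self.msi_pixel_index = np.asarray(self.msi_pixel_index, dtype=int)
        self.spot_index = np.asarray(self.spot_index, dtype=int)
        self.distance_px = np.asarray(self.distance_px, dtype=float)
        self.unpaired_msi_pixels = np.asarray(self.unpaired_msi_pixels, dtype=int)
        if len(np.unique(self.msi_pixel_index)) != len(self.msi_pixel_index):
            raise ValueError("msi_pixel_index must be unique")
        if self.distance_px.size and (
            (self.distance_px < 0).any() or (self.distance_px > self.max_dist_px).any()
        ):
            raise ValueError("pair distance outside [0, max_dist_px]")

    def __len__(self) -> int:
        return len(self.msi_pixel_index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "msi_idx": self.msi_pixel_index,
                "spot_idx": self.spot_index,
                "distance_px": self.distance_px,
            }
        )


def pair_modalities(
    msi_xy: np.ndarray, spot_xy: np.ndarray, cfg: PipelineConfig
) -> PairMap:
    """Pair each MSI pixel with one RNA spot.

    For each MSI pixel: its ``cfg.knn_k`` nearest spots are found by
    Euclidean distance, candidates farther than ``cfg.max_pair_dist_px`` are
    dropped, and the single closest surviving spot is kept (exact distance
    ties broken by lower spot index). Pixels with no surviving candidate are
    reported as unpaired. Spots may be reused across pixels.
    """
    msi_xy = np.atleast_2d(np.asarray(msi_xy, dtype=float))
    spot_xy = np.atleast_2d(np.asarray(spot_xy, dtype=float))
    if len(spot_xy) == 0:
        raise ValueError("empty spot set")
    if len(msi_xy) == 0:
        raise ValueError("empty MSI pixel set")

    k = min(cfg.knn_k, len(spot_xy))
    tree = cKDTree(spot_xy)
    dist, idx = tree.query(msi_xy, k=k)
    dist = np.atleast_2d(dist.T).T if dist.ndim == 1 else dist
    idx = np.atleast_2d(idx.T).T if idx.ndim == 1 else idx

    pixels, spots, dists, unpaired = [], [], [], []
    for i in range(len(msi_xy)):
        ok = dist[i] <= cfg.max_pair_dist_px
        if not ok.any():
            unpaired.append(i)
            continue
        cand_d, cand_i = dist[i][ok], idx[i][ok]
        dmin = cand_d.min()
        best_spot = cand_i[cand_d == dmin].min()  # exact ties: lower spot index
        pixels.append(i)
        spots.append(int(best_spot))
        dists.append(float(dmin))
    return PairMap(
        msi_pixel_index=np.array(pixels, dtype=int),
        spot_index=np.array(spots, dtype=int),
        distance_px=np.array(dists, dtype=float),
        unpaired_msi_pixels=np.array(unpaired, dtype=int),
        max_dist_px=cfg.max_pair_dist_px,
    )


def suggest_distance_cutoff(distances: np.ndarray, n_bins: int = 64) -> float:
    """Advisory Otsu threshold on the nearest-neighbor-distance histogram.

    Mirrors the published practice of reading the cutoff off the distance
    histogram; ``cfg.max_pair_dist_px`` always governs the actual pairing.
    On a well-separated bimodal histogram the Otsu objective is flat across
    the empty gap between the modes; the midpoint of that maximizing
    plateau is returned (so the suggestion sits mid-gap rather than hugging
    the near mode). Scale-equivariant: scaling all distances by c scales
    the threshold by c.
    """
    distances = np.asarray(distances, dtype=float)
    if len(distances) < 50:
        raise ValueError(f"need at least 50 distances, got {len(distances)}")
    if np.allclose(distances, distances[0]):
        warnings.warn("all distances identical; threshold is degenerate", stacklevel=2)
        return float(distances[0])
    counts, edges = np.histogram(distances, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    # between-class variance for every split "class 0 = bins <= k"
    w = counts / counts.sum()
    w0 = np.cumsum(w)[:-1]
    w1 = 1.0 - w0
    mu_cum = np.cumsum(w * centers)
    mu_total = mu_cum[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = mu_cum[:-1] / w0
        mu1 = (mu_total - mu_cum[:-1]) / w1
        objective = w0 * w1 * (mu0 - mu1) ** 2
    objective = np.nan_to_num(objective, nan=-np.inf)
    top = objective.max()
    plateau = np.flatnonzero(objective >= top * (1 - 1e-12))
    return float((centers[plateau[0]] + centers[plateau[-1]]) / 2)


def assemble_multimodal(
    section: SRTSection,
    normed: np.ndarray,
    raster: MSIRaster,
    pairs: PairMap,
) -> MultimodalDataset:
    """Subset both assays by a PairMap into one aligned paired dataset.

    Observation i carries the genes of the paired spot and the peaks of MSI
    pixel i; spots matched by several pixels are duplicated column-wise.
    Observations are ordered by ascending MSI pixel index.
    """
    if len(pairs) == 0:
        raise ValueError("empty PairMap: nothing to assemble")
    if pairs.msi_pixel_index.max() >= raster.n_pixels:
        raise IndexError("PairMap references an MSI pixel outside the raster")
    if pairs.spot_index.max() >= section.n_spots:
        raise IndexError("PairMap references a spot outside the section")

    order = np.argsort(pairs.msi_pixel_index)
    px = pairs.msi_pixel_index[order]
    sp = pairs.spot_index[order]
    d = pairs.distance_px[order]
    if (d > pairs.max_dist_px).any():
        raise ValueError("pair distance exceeds the configured cutoff")

    return MultimodalDataset(
        gene_counts=section.counts[:, sp],
        gene_norm=normed[:, sp],
        gene_ids=section.gene_ids,
        peak_intensities=raster.intensities[:, px],
        mz=raster.mz,
        obs_xy=section.spot_xy[sp],
        obs_barcodes=section.barcodes[sp],
        obs_msi_pixel=px,
        pair_distance_px=d,
        annotations=None if section.annotations is None else section.annotations[sp],
    )
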