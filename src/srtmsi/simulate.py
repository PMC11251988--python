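"""Synthetic paired SRT + MSI sections with known ground truth.

The generator emulates the structure of a same-section spatial multimodal
experiment on a rodent brain section: a hexagonal lattice of barcoded spots
with domain-structured negative-binomial counts; an MSI peak raster on its
own pitch, observed in a rotated/scaled/translated native coordinate frame
with off-tissue background pixels; a configurable set of planted peak-gene
links whose population Pearson correlation is exact by construction (the
link is induced at the level of the realized normalized expression); and a
unilateral lesion that depletes one peak in one hemisphere, mimicking a
6-OHDA-style dopamine depletion.

Every generator is a pure function of its configuration (including the
seed): the same config yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .datatypes import MSIRaster, SRTSection
from .register import LandmarkPairs, SimilarityTransform2D
from .srt import normalize_logcpm

_SQRT3_2 = np.sqrt(3.0) / 2.0


def _default_transform() -> SimilarityTransform2D:
    return SimilarityTransform2D(scale=2.0, rotation_rad=0.06, translation=(150.0, -80.0))


def _default_links() -> list[tuple[int, int, float]]:
    return [(0, 100, 0.8)]


@dataclass
class SynthConfig:
    """Study conditions for one synthetic paired section.

    Defaults give ~1,000 spots (32 x 32 hex lattice at 100 px pitch,
    mirroring 100 um spot spacing at full resolution), 2,000 genes with
    four row-band tissue domains (5% of genes per domain at a 4x mean
    shift), 50 peaks with one planted peak-gene link at true r = 0.8, a
    left-hemisphere lesion depleting peak 1 by 80%, and an MSI raster on
    the same 100 px pitch under a scale-2/6-degree-ish similarity
    transform with 300 background pixels.
    """

    n_spot_rows: int = 32
    n_spot_cols: int = 32
    spot_pitch_px: float = 100.0
    n_genes: int = 2000
    n_mito_genes: int = 13
    mito_count_frac: float = 0.05
    n_peaks: int = 50
    nb_dispersion: float = 2.0       # NB shape; variance = mu + mu^2 / dispersion
    n_domains: int = 4
    domain_marker_frac: float = 0.05
    domain_fold: float = 4.0
    planted_links: list[tuple[int, int, float]] = field(default_factory=_default_links)
    lesion_peak_index: int = 1
    lesion_depletion: float = 0.8
    true_transform: SimilarityTransform2D = field(default_factory=_default_transform)
    msi_pitch_px: float = 100.0
    n_background_pixels: int = 300
    n_landmarks: int = 8
    landmark_jitter_px: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spot_rows < 1 or self.n_spot_cols < 1:
            raise ValueError("spot grid must be at least 1 x 1")
        if self.spot_pitch_px <= 0 or self.msi_pitch_px <= 0:
            raise ValueError("pitches must be positive")
        if self.n_mito_genes >= self.n_genes:
            raise ValueError("n_mito_genes must be smaller than n_genes")
        if not 0.0 <= self.lesion_depletion <= 1.0:
            raise ValueError("lesion_depletion must lie in [0, 1]")
        genes = [g for _, g, _ in self.planted_links]
        if len(set(genes)) != len(genes):
            raise ValueError("planted gene indices must be distinct")
        n_regular = self.n_genes - self.n_mito_genes
        for p, g, r in self.planted_links:
            if not 0 < r < 1:
                raise ValueError(f"planted true_r must lie in (0, 1), got {r}")
            if not 0 <= p < self.n_peaks:
                raise ValueError(f"planted peak index {p} out of range")
            if not 0 <= g < n_regular:
                raise ValueError(f"planted gene index {g} out of range")
        if not 0 <= self.lesion_peak_index < self.n_peaks:
            raise ValueError("lesion_peak_index out of range")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    true_transform: SimilarityTransform2D
    pixel_xy_common: np.ndarray      # true common-frame coords of every pixel
    nearest_spot: np.ndarray         # per pixel; -1 for background pixels
    offtissue: np.ndarray            # boolean per pixel
    planted_links: list[tuple[int, str, float]]  # (peak_index, gene_id, true_r)
    domain: np.ndarray               # per spot, "domain_0".."domain_{k-1}"
    hemisphere: np.ndarray           # per spot, "intact" | "lesioned"


def _hex_lattice(n_rows: int, n_cols: int, pitch: float) -> np.ndarray:
    """Hexagonal-offset lattice: odd rows shifted half a pitch rightward."""
    r, c = np.mgrid[0:n_rows, 0:n_cols]
    x = c * pitch + (r % 2) * pitch / 2.0
    y = r * pitch * _SQRT3_2
    return np.column_stack([x.ravel(), y.ravel()]).astype(float)


def gene_names(cfg: SynthConfig) -> np.ndarray:
    regular = [f"gene-{i:04d}" for i in range(cfg.n_genes - cfg.n_mito_genes)]
    mito = [f"mt-{i + 1}" for i in range(cfg.n_mito_genes)]
    return np.array(regular + mito, dtype=object)


def gene_programs(cfg: SynthConfig) -> tuple[np.ndarray, list[np.ndarray]]:
    """Deterministic gene structure of a section: the log-normal baseline
    mean per gene (mt-* genes scaled to their target count share) and the
    marker-gene index set of each domain."""
    rng = np.random.default_rng(cfg.seed)
    n_regular = cfg.n_genes - cfg.n_mito_genes
    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    mito_total = cfg.mito_count_frac / (1 - cfg.mito_count_frac) * baseline[:n_regular].sum()
    baseline[n_regular:] *= mito_total / baseline[n_regular:].sum()
    n_markers = max(1, int(round(cfg.domain_marker_frac * n_regular)))
    marker_sets = [
        rng.choice(n_regular, size=n_markers, replace=False)
        for _ in range(cfg.n_domains)
    ]
    return baseline, marker_sets


def generate_srt(cfg: SynthConfig, noise_seed: int | None = None) -> SRTSection:
    """Simulate one spatial transcriptomics section.

    Counts are negative binomial (gamma-Poisson) with a log-normal baseline
    mean per gene; each tissue domain (horizontal row band) up-regulates its
    own random 5% of genes by ``domain_fold``. Mitochondrial genes are named
    ``mt-*`` and scaled so their expected count share is ``mito_count_frac``.

    The gene programs (baseline means, domain marker sets) are drawn from
    ``cfg.seed``; the count noise is drawn from ``noise_seed`` (defaulting
    to ``cfg.seed``), so two calls with different ``noise_seed`` emulate
    consecutive replicate sections: shared expression structure,
    independent sampling noise.
    """
    noise_rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed if noise_seed is None else noise_seed, 65537])
    )
    n_spots = cfg.n_spot_rows * cfg.n_spot_cols

    spot_xy = _hex_lattice(cfg.n_spot_rows, cfg.n_spot_cols, cfg.spot_pitch_px)
    r_idx, c_idx = np.divmod(np.arange(n_spots), cfg.n_spot_cols)
    domain = (r_idx * cfg.n_domains) // cfg.n_spot_rows

    center_x = spot_xy[:, 0].mean()
    hemisphere = np.where(spot_xy[:, 0] < center_x, "lesioned", "intact")

    baseline, marker_sets = gene_programs(cfg)
    fold = np.ones((cfg.n_genes, n_spots))
    for d, markers in enumerate(marker_sets):
        fold[np.ix_(markers, np.flatnonzero(domain == d))] = cfg.domain_fold
    mu = baseline[:, None] * fold

    shape = cfg.nb_dispersion
    counts = noise_rng.poisson(noise_rng.gamma(shape=shape, scale=mu / shape))

    annotations = np.array(
        [f"domain_{d}|{h}" for d, h in zip(domain, hemisphere)], dtype=object
    )
    return SRTSection(
        counts=counts.astype(np.int64),
        gene_ids=gene_names(cfg),
        barcodes=np.array([f"spot-{i:05d}" for i in range(n_spots)], dtype=object),
        spot_xy=spot_xy,
        array_rc=np.column_stack([r_idx, c_idx]),
        in_tissue=np.ones(n_spots, dtype=bool),
        annotations=annotations,
    )


def _smooth_field(xy: np.ndarray, rng: np.random.Generator, n_waves: int = 4) -> np.ndarray:
    """Low-frequency random field (sum of plane waves), roughly unit scale."""
    extent = max(np.ptp(xy[:, 0]), np.ptp(xy[:, 1]), 1.0)
    f = np.zeros(len(xy))
    for _ in range(n_waves):
        wavelength = extent / rng.uniform(0.5, 3.0)
        direction = rng.normal(size=2)
        direction /= np.linalg.norm(direction)
        phase = rng.uniform(0, 2 * np.pi)
        f += rng.normal() * np.cos(2 * np.pi * (xy @ direction) / wavelength + phase)
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_msi(
    cfg: SynthConfig, srt: SRTSection, noise_seed: int | None = None
) -> tuple[MSIRaster, GroundTruth]:
    """Simulate the MSI raster paired with a generated section.

    Tissue pixels lie on a hex lattice at ``msi_pitch_px`` over the spot
    footprint (with equal pitches and an identity transform every pixel
    coincides with its generating spot); their stored coordinates are
    MSI-native, i.e. the inverse of ``true_transform`` applied to the
    common-frame positions. Planted peaks are affine images of
    ``true_r * z_gene + sqrt(1 - true_r^2) * noise`` where ``z_gene`` is the
    z-scored realized log-normalized expression of the linked gene at the
    nearest spot, so the population correlation equals ``true_r`` exactly.
    Unlinked peaks are smooth spatial fields plus white noise. The lesion
    peak is multiplied by ``1 - lesion_depletion`` over the lesioned
    hemisphere, and background pixels carry near-zero noise.

    As in :func:`generate_srt`, peak structure (m/z axis, per-peak scales,
    smooth fields) comes from ``cfg.seed`` while measurement noise comes
    from ``noise_seed``, so different noise seeds emulate consecutive
    replicate sections.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7919]))
    noise_rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed if noise_seed is None else noise_seed, 7919, 1])
    )
    spot_xy = srt.spot_xy

    n_rows = int(np.floor(spot_xy[:, 1].max() / (cfg.msi_pitch_px * _SQRT3_2) + 1e-9)) + 1
    n_cols = int(np.floor(spot_xy[:, 0].max() / cfg.msi_pitch_px + 1e-9)) + 1
    tissue_common = _hex_lattice(n_rows, n_cols, cfg.msi_pitch_px)
    n_tissue = len(tissue_common)

    nearest = cKDTree(spot_xy).query(tissue_common)[1]

    # background ring around the tissue footprint
    margin_lo, margin_hi = 2 * cfg.msi_pitch_px, 6 * cfg.msi_pitch_px
    xmin, ymin = spot_xy.min(axis=0)
    xmax, ymax = spot_xy.max(axis=0)
    bg = []
    while len(bg) < cfg.n_background_pixels:
        pt = noise_rng.uniform(
            [xmin - margin_hi, ymin - margin_hi], [xmax + margin_hi, ymax + margin_hi]
        )
        outside = (
            pt[0] < xmin - margin_lo or pt[0] > xmax + margin_lo
            or pt[1] < ymin - margin_lo or pt[1] > ymax + margin_lo
        )
        if outside:
            bg.append(pt)
    bg_common = np.array(bg) if bg else np.empty((0, 2))

    pixel_common = np.vstack([tissue_common, bg_common])
    n_pixels = len(pixel_common)
    offtissue = np.zeros(n_pixels, dtype=bool)
    offtissue[n_tissue:] = True

    normed = normalize_logcpm(srt)
    gene_index = {g: i for i, g in enumerate(srt.gene_ids)}

    linked_peaks = {p: (g, r) for p, g, r in cfg.planted_links}
    latent = np.empty((cfg.n_peaks, n_tissue))
    for p in range(cfg.n_peaks):
        if p in linked_peaks:
            g, true_r = linked_peaks[p]
            gvals = normed[g]
            z = (gvals - gvals.mean()) / gvals.std()
            latent[p] = (
                true_r * z[nearest]
                + np.sqrt(1 - true_r ** 2) * noise_rng.standard_normal(n_tissue)
            )
        else:
            latent[p] = (
                _smooth_field(tissue_common, rng)
                + 0.3 * noise_rng.standard_normal(n_tissue)
            )

    # affine map to a positive intensity scale (Pearson-preserving per peak)
    peak_scale = rng.lognormal(mean=np.log(100.0), sigma=0.5, size=cfg.n_peaks)
    lo = latent.min(axis=1, keepdims=True)
    span = np.maximum(latent.max(axis=1, keepdims=True) - lo, 1e-12)
    tissue_int = (latent - lo + 0.05 * span) * peak_scale[:, None]

    hemisphere = np.array([str(a).split("|")[1] for a in srt.annotations], dtype=object)
    lesioned_pixels = hemisphere[nearest] == "lesioned"
    tissue_int[cfg.lesion_peak_index, lesioned_pixels] *= 1 - cfg.lesion_depletion

    bg_sigma = 0.01 * np.median(tissue_int, axis=1)
    bg_int = np.abs(
        noise_rng.normal(scale=bg_sigma[:, None], size=(cfg.n_peaks, len(bg_common)))
    )

    mz = 150.0 + np.cumsum(rng.uniform(1.0, 12.0, size=cfg.n_peaks))
    native = cfg.true_transform.inverse().apply(pixel_common)

    raster = MSIRaster(
        intensities=np.hstack([tissue_int, bg_int]),
        mz=mz,
        pixel_xy=native,
        pitch_um=100.0,
    )
    truth = GroundTruth(
        true_transform=cfg.true_transform,
        pixel_xy_common=pixel_common,
        nearest_spot=np.concatenate([nearest, -np.ones(len(bg_common), dtype=int)]),
        offtissue=offtissue,
        planted_links=[(p, str(srt.gene_ids[g]), r) for p, g, r in cfg.planted_links],
        domain=np.array([str(a).split("|")[0] for a in srt.annotations], dtype=object),
        hemisphere=hemisphere,
    )
    return raster, truth


def generate_landmarks(cfg: SynthConfig, truth: GroundTruth) -> LandmarkPairs:
    """Sample landmark pairs from tissue pixels with Gaussian target jitter."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 104729]))
    tissue = np.flatnonzero(~truth.offtissue)
    n = max(cfg.n_landmarks, 2)
    chosen = rng.choice(tissue, size=min(n, len(tissue)), replace=False)
    source = truth.true_transform.inverse().apply(truth.pixel_xy_common[chosen])
    target = truth.pixel_xy_common[chosen] + rng.normal(
        scale=cfg.landmark_jitter_px, size=(len(chosen), 2)
    )
    return LandmarkPairs(source_xy=source, target_xy=target)


def generate_two_block_embedding(
    seed: int = 0,
    n_genes_per_block: int = 10,
    n_peaks_per_block: int = 5,
    d: int = 10,
    noise: float = 0.05,
):
    """Two orthogonal planted feature blocks for module-recovery checks.

    Block A lives in the first d/2 embedding coordinates, block B in the
    last d/2 (hence exactly zero cosine similarity across blocks); gene
    vectors scatter tightly around each block center and each peak is an
    exact copy of one of its block's genes. Returns the embedding and the
    ground-truth block label per feature id.
    """
    from .modules import FeatureEmbedding

    rng = np.random.default_rng(seed)
    half = d // 2
    center_a = np.concatenate([rng.normal(size=half), np.zeros(d - half)])
    center_b = np.concatenate([np.zeros(half), rng.normal(size=d - half)])

    def scatter(center: np.ndarray, n: int) -> np.ndarray:
        pts = center[None, :] + noise * rng.normal(size=(n, d))
        mask = center != 0  # keep each block inside its own subspace
        return pts * mask[None, :]

    genes_a = scatter(center_a, n_genes_per_block)
    genes_b = scatter(center_b, n_genes_per_block)
    peaks_a = genes_a[rng.choice(n_genes_per_block, n_peaks_per_block, replace=False)]
    peaks_b = genes_b[rng.choice(n_genes_per_block, n_peaks_per_block, replace=False)]

    n_g = 2 * n_genes_per_block
    ids = [f"g{i}" for i in range(n_g)] + [f"p{i}" for i in range(2 * n_peaks_per_block)]
    types = ["gene"] * n_g + ["peak"] * 2 * n_peaks_per_block
    labels = (
        ["A"] * n_genes_per_block + ["B"] * n_genes_per_block
        + ["A"] * n_peaks_per_block + ["B"] * n_peaks_per_block
    )
    embedding = FeatureEmbedding(
        feature_ids=ids,
        feature_types=types,
        coords=np.vstack([genes_a, genes_b, peaks_a, peaks_b]),
    )
    return embedding, dict(zip(ids, labels))


def null_config(seed: int = 0, n_genes: int = 2000) -> SynthConfig:
    """A complete-null configuration: no planted links, no lesion, a single
    domain (hence no spatial gene programs), ~500 spots."""
    return SynthConfig(
        n_spot_rows=23,
        n_spot_cols=22,
        n_genes=n_genes,
        n_domains=1,
        domain_fold=1.0,
        planted_links=[],
        lesion_depletion=0.0,
        n_background_pixels=0,
        seed=seed,
    )


def small_raster_config(seed: int = 0) -> SynthConfig:
    """A compact raster (about 200 tissue pixels, 100 background) for
    off-tissue detection checks."""
    return SynthConfig(
        n_spot_rows=14,
        n_spot_cols=15,
        n_genes=300,
        n_peaks=30,
        n_background_pixels=100,
        seed=seed,
    )
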