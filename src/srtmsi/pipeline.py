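"""End-to-end orchestration: QC -> register -> pair -> assemble.

The stage order follows the published workflow: SRT spots and genes are
QC-filtered; MSI background pixels are removed by PCA before alignment; the
MSI-to-common-frame similarity transform is fitted to landmarks; each
remaining MSI pixel is paired with its closest QC-passing spot within the
distance cutoff; and the paired observations are assembled into one
two-assay dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .datatypes import MSIRaster, MultimodalDataset, SRTSection
from .msi import flag_offtissue
from .register import (
    LandmarkPairs,
    PairMap,
    SimilarityTransform2D,
    fit_similarity,
    pair_modalities,
)
from .srt import SpotFilterLog, filter_genes, filter_spots, normalize_logcpm


@dataclass
class PipelineResult:
    section: SRTSection          # QC-passing spots and genes
    normed: np.ndarray           # log-normalized expression of `section`
    spot_log: SpotFilterLog
    n_genes_removed: int
    raster: MSIRaster            # on-tissue pixels only
    offtissue: np.ndarray        # flags on the input raster's pixels
    transform: SimilarityTransform2D
    pairs: PairMap
    mm: MultimodalDataset


def run_pipeline(
    section: SRTSection,
    raster: MSIRaster,
    landmarks: LandmarkPairs,
    cfg: PipelineConfig,
    species: str = "mouse",
    exclude_barcodes: set[str] | None = None,
) -> PipelineResult:
    section, spot_log = filter_spots(section, cfg, exclude_barcodes)
    section, n_removed = filter_genes(section, species)
    normed = normalize_logcpm(section)

    off = flag_offtissue(raster)
    tissue = raster.subset_pixels(np.flatnonzero(~off))

    transform = fit_similarity(landmarks)
    msi_xy = transform.apply(tissue.pixel_xy)
    pairs = pair_modalities(msi_xy, section.spot_xy, cfg)

    from .register import assemble_multimodal

    mm = assemble_multimodal(section, normed, tissue, pairs)
    return PipelineResult(
        section=section,
        normed=normed,
        spot_log=spot_log,
        n_genes_removed=n_removed,
        raster=tissue,
        offtissue=off,
        transform=transform,
        pairs=pairs,
        mm=mm,
    )
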