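"""In-memory containers for the two assays.

The common coordinate frame throughout the package is full-resolution
H&E-image pixel space: origin top-left, x rightward, y downward, 0-based —
the convention of the Visium tissue-positions CSV. MSI rasters carry their
own native pixel coordinates until a similarity transform maps them into the
common frame (see :mod:`srtmsi.register`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SRTSection:
    """A spatially resolved transcriptomics section.

    counts : (n_genes, n_spots) non-negative integer matrix
    gene_ids : unique gene symbols, one per row
    barcodes : unique spot barcodes, one per column
    spot_xy : (n_spots, 2) float spot centers in common-frame pixels
    array_rc : (n_spots, 2) integer array row/col of each spot
    in_tissue : boolean per spot, from the positions file
    annotations : optional per-spot string labels (region, hemisphere, cluster)
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    barcodes: np.ndarray
    spot_xy: np.ndarray
    array_rc: np.ndarray
    in_tissue: np.ndarray
    annotations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.spot_xy = np.asarray(self.spot_xy, dtype=float)
        self.array_rc = np.asarray(self.array_rc, dtype=int)
        self.in_tissue = np.asarray(self.in_tissue, dtype=bool)
        if self.annotations is not None:
            self.annotations = np.asarray(self.annotations, dtype=object)
        ng, ns = self.counts.shape
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if len(self.gene_ids) != ng:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {ng} count rows")
        if len(self.barcodes) != ns:
            raise ValueError(f"{len(self.barcodes)} barcodes for {ns} count columns")
        if len(set(self.barcodes)) != ns:
            raise ValueError("barcodes are not unique")
        if len(set(self.gene_ids)) != ng:
            raise ValueError("gene ids are not unique")
        if self.spot_xy.shape != (ns, 2) or not np.isfinite(self.spot_xy).all():
            raise ValueError("spot_xy must be finite with shape (n_spots, 2)")
        if self.array_rc.shape != (ns, 2):
            raise ValueError("array_rc must have shape (n_spots, 2)")
        if self.in_tissue.shape != (ns,):
            raise ValueError("in_tissue must have one flag per spot")
        if self.annotations is not None and self.annotations.shape != (ns,):
            raise ValueError("annotations must have one label per spot")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    def subset_spots(self, idx: np.ndarray) -> "SRTSection":
        idx = np.asarray(idx)
        return SRTSection(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
            barcodes=self.barcodes[idx],
            spot_xy=self.spot_xy[idx],
            array_rc=self.array_rc[idx],
            in_tissue=self.in_tissue[idx],
            annotations=None if self.annotations is None else self.annotations[idx],
        )

    def subset_genes(self, idx: np.ndarray) -> "SRTSection":
        idx = np.asarray(idx)
        return SRTSection(
            counts=self.counts[idx, :],
            gene_ids=self.gene_ids[idx],
            barcodes=self.barcodes,
            spot_xy=self.spot_xy,
            array_rc=self.array_rc,
            in_tissue=self.in_tissue,
            annotations=self.annotations,
        )


@dataclass
class MSIRaster:
    """A mass spectrometry imaging peak raster.

    intensities : (n_peaks, n_pixels) non-negative float matrix
    mz : strictly increasing m/z value per peak, Daltons
    pixel_xy : (n_pixels, 2) float pixel centers, MSI-native units
    pitch_um : lateral resolution in micrometres
    matrix_name : MALDI matrix used (e.g. "FMP-10", "9-AA", "DHB")
    polarity : "positive" or "negative" ion mode
    """

    intensities: np.ndarray
    mz: np.ndarray
    pixel_xy: np.ndarray
    pitch_um: float = 100.0
    matrix_name: str = "FMP-10"
    polarity: str = "positive"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mz = np.asarray(self.mz, dtype=float)
        self.pixel_xy = np.asarray(self.pixel_xy, dtype=float)
        npk, npx = self.intensities.shape
        if len(self.mz) != npk:
            raise ValueError(f"{len(self.mz)} m/z values for {npk} intensity rows")
        if npk > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz must be strictly increasing")
        if self.pixel_xy.shape != (npx, 2):
            raise ValueError("pixel_xy must have shape (n_pixels, 2)")
        if len(set(map(tuple, self.pixel_xy))) != npx:
            raise ValueError("pixel coordinates are not unique")
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be positive")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive|negative, got {self.polarity!r}")

    @property
    def n_peaks(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.intensities.shape[1]

    def subset_pixels(self, idx: np.ndarray) -> "MSIRaster":
        idx = np.asarray(idx)
        return MSIRaster(
            intensities=self.intensities[:, idx],
            mz=self.mz,
            pixel_xy=self.pixel_xy[idx],
            pitch_um=self.pitch_um,
            matrix_name=self.matrix_name,
            polarity=self.polarity,
        )


@dataclass
class MultimodalDataset:
    """Paired gene/peak observations after cross-modality pairing.

    Each observation is one MSI pixel matched to one RNA spot; a spot matched
    by several pixels appears in several columns. Both assays share the same
    observation order (ascending MSI pixel index).
    """

    gene_counts: np.ndarray          # (n_genes, n_obs) raw counts
    gene_norm: np.ndarray            # (n_genes, n_obs) log-normalized values
    gene_ids: np.ndarray
    peak_intensities: np.ndarray     # (n_peaks, n_obs)
    mz: np.ndarray
    obs_xy: np.ndarray               # common-frame coordinates of the RNA spots
    obs_barcodes: np.ndarray         # barcode of the paired spot (may repeat)
    obs_msi_pixel: np.ndarray        # MSI pixel index of each observation
    pair_distance_px: np.ndarray
    annotations: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.gene_counts.shape[1]
        for name in ("gene_norm", "peak_intensities"):
            if getattr(self, name).shape[1] != n:
                raise ValueError(f"{name} has {getattr(self, name).shape[1]} columns, expected {n}")
        for name in ("obs_xy", "obs_barcodes", "obs_msi_pixel", "pair_distance_px"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} has {len(getattr(self, name))} entries, expected {n}")

    @property
    def n_obs(self) -> int:
        return self.gene_counts.shape[1]
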