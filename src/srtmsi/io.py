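"""Readers and writers for the on-disk formats the pipeline touches.

Spatial transcriptomics sections use the standard Visium output layout:
a MatrixMarket counts triplet (``matrix.mtx``), gene and barcode lists
(``features.tsv`` / ``barcodes.tsv``) and a ``tissue_positions.csv`` with
columns barcode, in_tissue, array_row, array_col, pxl_row_in_fullres,
pxl_col_in_fullres. MSI rasters are read either from continuous-mode imzML
(shared m/z axis) or from a plain peak-table CSV with columns ``x``, ``y``
followed by one intensity column per peak, labeled by its m/z value.

Readers never reorder spots or pixels, with one documented exception: MSI
peaks are sorted by ascending m/z.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import MSIRaster, SRTSection


class FormatError(ValueError):
    """A file is missing, empty, or not in the expected dialect."""


class ConsistencyError(ValueError):
    """Files of one dataset disagree with each other."""


_POSITIONS_COLUMNS = [
    "barcode", "in_tissue", "array_row", "array_col",
    "pxl_row_in_fullres", "pxl_col_in_fullres",
]


def _require(path: str, kind: str) -> str:
    if not os.path.exists(path):
        raise FormatError(f"missing {kind} file: {path}")
    return path


def read_srt_dir(path: str) -> SRTSection:
    """Read a Visium-style directory into an :class:`SRTSection`.

    Spots are ordered as in the barcode file; spot_xy is taken from the
    full-resolution pixel columns of the positions CSV (x = pxl_col,
    y = pxl_row). Off-tissue spots are retained but flagged.
    """
    mtx_path = _require(os.path.join(path, "matrix.mtx"), "MatrixMarket matrix")
    genes_path = _require(os.path.join(path, "features.tsv"), "gene list")
    barcodes_path = _require(os.path.join(path, "barcodes.tsv"), "barcode list")
    pos_path = _require(os.path.join(path, "tissue_positions.csv"), "tissue positions")

    if os.path.getsize(mtx_path) == 0:
        raise FormatError(f"empty matrix file: {mtx_path}")
    try:
        counts = scipy.io.mmread(mtx_path)
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise FormatError(f"cannot parse MatrixMarket file {mtx_path}: {exc}") from exc
    counts = np.asarray(scipy.sparse.coo_matrix(counts).todense())

    gene_ids = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).to_numpy()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).to_numpy()
    pos = pd.read_csv(pos_path)
    missing = [c for c in _POSITIONS_COLUMNS if c not in pos.columns]
    if missing:
        raise FormatError(f"tissue positions CSV lacks columns {missing}")

    if counts.shape != (len(gene_ids), len(barcodes)):
        raise ConsistencyError(
            f"matrix is {counts.shape} but lists give "
            f"{len(gene_ids)} genes x {len(barcodes)} barcodes"
        )
    pos = pos.set_index("barcode")
    absent = [b for b in barcodes if b not in pos.index]
    if absent:
        raise ConsistencyError(
            f"{len(absent)} barcodes absent from tissue positions (first: {absent[0]})"
        )
    pos = pos.loc[barcodes]

    return SRTSection(
        counts=counts.astype(np.int64),
        gene_ids=gene_ids,
        barcodes=barcodes,
        spot_xy=np.column_stack(
            [pos["pxl_col_in_fullres"].to_numpy(float), pos["pxl_row_in_fullres"].to_numpy(float)]
        ),
        array_rc=np.column_stack(
            [pos["array_row"].to_numpy(int), pos["array_col"].to_numpy(int)]
        ),
        in_tissue=pos["in_tissue"].to_numpy().astype(bool),
    )


def write_srt_dir(section: SRTSection, path: str) -> None:
    """Write a section in the layout :func:`read_srt_dir` consumes."""
    os.makedirs(path, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(path, "matrix.mtx"),
        scipy.sparse.coo_matrix(section.counts),
        field="integer",
    )
    pd.Series(section.gene_ids).to_csv(
        os.path.join(path, "features.tsv"), sep="\t", header=False, index=False
    )
    pd.Series(section.barcodes).to_csv(
        os.path.join(path, "barcodes.tsv"), sep="\t", header=False, index=False
    )
    pd.DataFrame(
        {
            "barcode": section.barcodes,
            "in_tissue": section.in_tissue.astype(int),
            "array_row": section.array_rc[:, 0],
            "array_col": section.array_rc[:, 1],
            "pxl_row_in_fullres": np.round(section.spot_xy[:, 1], 6),
            "pxl_col_in_fullres": np.round(section.spot_xy[:, 0], 6),
        }
    ).to_csv(os.path.join(path, "tissue_positions.csv"), index=False)


def _read_msi_csv(path: str) -> MSIRaster:
    table = pd.read_csv(path)
    if list(table.columns[:2]) != ["x", "y"]:
        raise FormatError(f"{path}: first two columns must be x, y")
    try:
        mz = np.array([float(c) for c in table.columns[2:]])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric m/z column header ({exc})") from exc
    if mz.size == 0:
        raise FormatError(f"{path}: no peak columns")
    pixel_xy = table[["x", "y"]].to_numpy(float)
    if len(set(map(tuple, pixel_xy))) != len(pixel_xy):
        raise ConsistencyError(f"{path}: duplicated (x, y) pixel coordinates")
    order = np.argsort(mz, kind="stable")
    return MSIRaster(
        intensities=table.iloc[:, 2:].to_numpy(float).T[order],
        mz=mz[order],
        pixel_xy=pixel_xy,
    )


def _read_msi_imzml(path: str) -> MSIRaster:
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(path)
    n = len(parser.coordinates)
    if n == 0:
        raise FormatError(f"{path}: imzML file contains no spectra")
    mz0, int0 = parser.getspectrum(0)
    mz0 = np.asarray(mz0, dtype=float)
    if len(set(parser.mzLengths)) != 1:
        raise FormatError(
            f"{path}: processed-mode imzML (per-pixel m/z axes) is not supported; "
            "a continuous-mode file with a shared m/z axis is required"
        )
    intensities = np.empty((len(mz0), n))
    intensities[:, 0] = int0
    for i in range(1, n):
        mz_i, int_i = parser.getspectrum(i)
        if not np.allclose(mz_i, mz0, atol=1e-6):
            raise FormatError(
                f"{path}: spectrum {i} has a different m/z axis; processed-mode "
                "imzML is not supported"
            )
        intensities[:, i] = int_i
    pixel_xy = np.array([(c[0], c[1]) for c in parser.coordinates], dtype=float)
    order = np.argsort(mz0, kind="stable")
    return MSIRaster(intensities=intensities[order], mz=mz0[order], pixel_xy=pixel_xy)


def read_msi(path: str, format: str | None = None) -> MSIRaster:
    """Read an MSI peak raster from continuous imzML or a peak-table CSV.

    Peaks are returned sorted by ascending m/z; pixel order is preserved.
    """
    _require(path, "MSI")
    if format is None:
        format = "imzml" if path.lower().endswith(".imzml") else "csv"
    if format == "csv":
        return _read_msi_csv(path)
    if format == "imzml":
        return _read_msi_imzml(path)
    raise ValueError(f"unknown MSI format {format!r}; expected 'imzml' or 'csv'")


def write_msi_csv(raster: MSIRaster, path: str) -> None:
    """Write the peak-table CSV dialect :func:`read_msi` consumes."""
    table = pd.DataFrame(
        {"x": np.round(raster.pixel_xy[:, 0], 6), "y": np.round(raster.pixel_xy[:, 1], 6)}
    )
    for j, mz in enumerate(raster.mz):
        table[f"{mz:.4f}"] = raster.intensities[j]
    table.to_csv(path, index=False)


def write_msi_imzml(raster: MSIRaster, path: str) -> None:
    """Write a continuous-mode imzML/ibd pair (integer pixel grid required)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    xy = raster.pixel_xy
    if not np.allclose(xy, np.round(xy)):
        raise ValueError("imzML requires integer pixel coordinates; use write_msi_csv")
    with ImzMLWriter(path, mode="continuous") as writer:
        for i in range(raster.n_pixels):
            writer.addSpectrum(
                raster.mz, raster.intensities[:, i],
                (int(round(xy[i, 0])), int(round(xy[i, 1])), 1),
            )


def write_multimodal_csv(mm, path: str) -> None:
    """Write a paired dataset as one flat CSV.

    Column layout: obs (MSI pixel index), barcode, x, y, pair_distance_px,
    annotation, then one ``gene:<id>`` column per gene (log-normalized) and
    one ``peak:<m/z>`` column per peak (intensity).
    """
    table = pd.DataFrame(
        {
            "obs": mm.obs_msi_pixel,
            "barcode": mm.obs_barcodes,
            "x": mm.obs_xy[:, 0],
            "y": mm.obs_xy[:, 1],
            "pair_distance_px": mm.pair_distance_px,
            "annotation": mm.annotations if mm.annotations is not None else "",
        }
    )
    for i, g in enumerate(mm.gene_ids):
        table[f"gene:{g}"] = mm.gene_norm[i]
    for j, mz in enumerate(mm.mz):
        table[f"peak:{mz:.4f}"] = mm.peak_intensities[j]
    table.to_csv(path, index=False)
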