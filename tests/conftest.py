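import numpy as np
import pytest

from srtmsi import MSIRaster, PipelineConfig, SRTSection, SynthConfig
from srtmsi import generate_msi, generate_srt


@pytest.fixture
def cfg():
    return PipelineConfig(seed=0)


def make_section(counts, gene_ids=None, spot_xy=None, in_tissue=None, annotations=None):
    counts = np.asarray(counts)
    ng, ns = counts.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(ng)]
    if spot_xy is None:
        spot_xy = np.column_stack([np.arange(ns, dtype=float), np.zeros(ns)])
    return SRTSection(
        counts=counts,
        gene_ids=np.array(gene_ids, dtype=object),
        barcodes=np.array([f"bc{i}" for i in range(ns)], dtype=object),
        spot_xy=spot_xy,
        array_rc=np.column_stack([np.zeros(ns, int), np.arange(ns)]),
        in_tissue=np.ones(ns, bool) if in_tissue is None else np.asarray(in_tissue, bool),
        annotations=annotations,
    )


def make_raster(intensities, mz=None, pixel_xy=None):
    intensities = np.asarray(intensities, float)
    npk, npx = intensities.shape
    if mz is None:
        mz = 150.0 + 10.0 * np.arange(npk)
    if pixel_xy is None:
        pixel_xy = np.column_stack([np.arange(npx, dtype=float), np.zeros(npx)])
    return MSIRaster(intensities=intensities, mz=np.asarray(mz, float), pixel_xy=pixel_xy)


@pytest.fixture
def tiny_section():
    rng = np.random.default_rng(0)
    return make_section(rng.poisson(3.0, size=(30, 12)))


@pytest.fixture(scope="session")
def default_synthetic():
    """One default-condition synthetic paired section, shared across tests."""
    scfg = SynthConfig(seed=0)
    srt = generate_srt(scfg)
    raster, truth = generate_msi(scfg, srt)
    return scfg, srt, raster, truth
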