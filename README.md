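# srtmsi

Same-section integration of spatially resolved transcriptomics (SRT) with
MALDI mass spectrometry imaging (MSI) metabolomics.

Spatial multimodal experiments acquire an m/z peak raster by MALDI-MSI and a
Visium-style barcoded-spot expression profile from the *same* tissue
section. The two assays live on different pixel grids in different
coordinate frames, so relating a metabolite image to gene expression
requires registration, cross-modality pairing, and statistics that respect
the paired design. This package implements that workflow for computational
biologists working with such data:

1. **QC** — spots with fewer than 50 unique genes or more than 38%
   mitochondrial counts are removed; hemoglobin-, ribosomal-protein-coding
   and *Malat1* genes are dropped; MSI background pixels are identified by
   PCA of the log pixel spectra and removed.
2. **Registration** — a similarity transform (rotation *R*, isotropic scale
   *s*, translation *t*; `p ↦ sRp + t`) is fitted to landmark pairs by the
   closed-form least-squares (Umeyama) solution, mapping MSI pixels into
   the spot coordinate frame.
3. **Pairing** — each MSI pixel finds its *k* = 5 nearest spots, candidate
   pairs farther than 35 px are discarded, and the single closest surviving
   spot is kept; a spot may be reused by several pixels. The result is a
   paired two-assay dataset.
4. **Correlation screen** — for a chosen peak, Pearson correlations
   `r(peak, gene)` across the paired observations, two-sided P from
   `t = r√((n−2)/(1−r²))`, Benjamini–Hochberg FDR, discoveries at q < 0.01.
5. **Module discovery** — genes (top 2,000 highly variable) and peaks are
   co-embedded by PCA (feature coordinates = loadings × singular values),
   each peak is linked to its ten nearest gene features by cosine distance,
   and spinglass community detection partitions the peak–gene graph into
   spatially co-detected modules.
6. **Concordance** — replicate agreement as Pearson correlations of
   log pseudobulk gene profiles and of log mean spectra.

A synthetic-data generator (`srtmsi.simulate`) produces paired sections
with known ground truth — a hex spot lattice with domain-structured
negative-binomial counts, an MSI raster under a known similarity transform
with off-tissue background, planted peak–gene links with exact population
correlation, and a unilateral lesion depleting one peak — so every stage
is testable end to end without external data.

## Worked example

```python
import srtmsi as sm

scfg = sm.SynthConfig(seed=0)              # ~1,000 spots, 2,000 genes, 50 peaks
srt = sm.generate_srt(scfg)
raster, truth = sm.generate_msi(scfg, srt)
landmarks = sm.generate_landmarks(scfg, truth)

cfg = sm.PipelineConfig(seed=0)
res = sm.run_pipeline(srt, raster, landmarks, cfg)

peak_mz = raster.mz[truth.planted_links[0][0]]
table = sm.peak_gene_correlation(res.mm, peak_mz, cfg)
print(table.head(3)[["gene", "r", "qval", "significant"]])
```

prints

```
        gene         r           qval  significant
0  gene-0100  0.790891  6.731692e-217         True
1  gene-0524  0.112308   2.906688e-01        False
2  gene-1258  0.105994   3.403303e-01        False
```

The planted gene (`gene-0100`, true r = 0.8) tops the ranking with an
estimated r ≈ 0.79 and is the only discovery at q < 0.01; all other genes
sit near the null. The fitted transform recovers the true scale 2.0 and
rotation 0.06 rad to about three decimals, and every tissue pixel pairs to
the spot nearest its true position (see `analysis/03_register_and_pair.py`).

The `analysis/` directory walks the full study as numbered drivers —
simulation, QC/concordance, registration/pairing, the correlation screen,
and module discovery — each printing what it found and writing its tables
under `results/`.

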