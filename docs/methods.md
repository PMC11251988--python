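# Methods

This note documents the models, parameter choices and numerical decisions
behind `srtmsi`, and what the synthetic validation does and does not show
about real data.

## Coordinate frames and data model

The common coordinate frame is full-resolution H&E-image pixel space:
origin top-left, x rightward, y downward, 0-based — the convention of the
Visium tissue-positions CSV, whose `pxl_col_in_fullres` /
`pxl_row_in_fullres` columns supply spot centers. MSI rasters keep their
native pixel coordinates until registration. Counts are dense integer
matrices (genes × spots); at the scale this package targets (thousands of
spots) dense arrays are simpler and fast enough. Gene identifiers are kept
as given; no symbol↔Ensembl mapping layer is provided. imzML support is
limited to continuous mode (one shared m/z axis); processed-mode files are
rejected with an explicit message, because peak picking and m/z alignment
belong to upstream vendor processing, not to this pipeline.

## Quality control

**Spots.** A spot is retained iff it detects ≥ 50 unique genes and its
mitochondrial count fraction is ≤ 0.38 (boundary values pass, matching the
strict "more than"/"less than" phrasing of the removal rule), it lies in
tissue, and its barcode is not explicitly excluded. Mitochondrial genes
are recognized by the case-insensitive symbol prefix `mt-`; "38%
mitochondrial genes" is read as a count fraction, not a unique-gene
fraction. The 38%/50 defaults are unusually permissive by single-cell
standards but appropriate for brain sections, where high mitochondrial
content is biological rather than artefactual.

**Genes.** Hemoglobin (`Hba/Hbb`, `HBA/HBB`), ribosomal protein
(`Rps/Rpl`, `RPS/RPL`) and `Malat1/MALAT1` genes are removed,
case-insensitively, with mouse and human pattern sets.

**MSI background.** Pixel spectra are log10(1+x) transformed (optionally
TIC-normalized first), centered, and projected onto the first principal
component. The PC1 scores are split by an exact two-cluster 1-D k-means —
the split of the sorted scores minimizing total within-class sum of
squares — and the cluster with the lower mean total intensity is flagged
off-tissue. The exact 1-D formulation needs no random initialization, so
the flagging is deterministic and invariant to pixel order; cluster
identity is decided by total intensity rather than score sign, so the
arbitrary sign of PC1 is immaterial. A manual total-intensity threshold
can override the PCA rule. If all pixels are identical, nothing is flagged
and a warning is emitted.

## Normalization and feature selection

Per-spot counts are scaled to 10,000 and log1p-transformed (log-CPM). The
original workflow used a heavier variance-stabilizing transform; log-CPM is
substituted deliberately — every downstream consumer (Pearson correlation,
rank-sum tests, PCA on z-scored features) requires only a monotone
per-spot normalization, and log-CPM keeps the pipeline dependency-light
and exactly reproducible.

Highly variable genes are ranked by variance standardized against a
mean–variance trend: a degree-2 polynomial fit of log10 variance on log10
mean across all expressed genes, with each gene scored as
variance / trend(mean). When the gene means do not spread (log10 range
≤ 0.1) the trend is unidentifiable and raw variance is used directly.
Constant genes are never selected while non-constant genes remain; ties
break lexicographically by gene id, so selection is fully deterministic.

## Marker ranking

One-vs-rest two-sided Wilcoxon rank-sum per cluster and gene. For up to 14
total observations the exact tie-aware permutation null of the rank sum is
enumerated; above that, the normal approximation with tie correction and
continuity correction is used, vectorized across genes. (The exact branch
exists because at 6-vs-6 the normal approximation can sit ~0.03 from the
discrete permutation null in the mid-p range — immaterial for significance
calls on hundreds of spots, but wrong as a ground-truth small-sample
answer.) Log2 fold changes are computed on de-logged means with a 1e-9
pseudocount; P values are Bonferroni-corrected over genes × clusters, and
a marker is significant iff log2FC > 0.25 and adjusted P < 0.01 (strict
inequalities).

## Registration and pairing

Landmark pairs (MSI-native → common frame) are fitted with the closed-form
least-squares similarity transform (orthogonal Procrustes with scale,
i.e. the Umeyama solution): with centered coordinates, SVD of the
cross-covariance gives the rotation, the trace of the singular values over
the source variance gives the scale. Reflections are disallowed by default
(the determinant is constrained to +1); tissue sections are rigid at the
100 µm scale, so a similarity transform replaces interactive alignment
without loss. Two non-coincident landmarks suffice (4 constraints for 4
degrees of freedom); coincident sources raise a degenerate-configuration
error.

Pairing follows a fixed order of operations: k = 5 nearest spots per MSI
pixel (cKDTree), candidates farther than 35 px discarded, then the single
closest surviving spot kept per pixel, with exact distance ties broken by
the lower spot index. Spots may be reused by multiple pixels — the mapping
is each-pixel→exactly-one-spot, many-to-one toward spots (pairing runs in
the MSI→RNA direction only; MSI rasters are the sparser modality). Pixels
with no surviving candidate are reported as unpaired. The 35 px cutoff is
interpreted in whatever frame the supplied spot pixel coordinates use —
for standard Visium positions files, full-resolution H&E pixels — and is
configurable. With k = 5 the procedure equals the brute-force all-pairs
rule whenever the true nearest spot is among the 5 nearest, which holds by
construction; the test suite asserts exact equality against the oracle.

`suggest_distance_cutoff` offers a data-driven cutoff: the Otsu threshold
of the 64-bin nearest-neighbor-distance histogram. On a well-separated
bimodal histogram the Otsu objective is flat across the empty gap between
modes; the midpoint of the maximizing plateau is returned so the
suggestion sits mid-gap instead of hugging the near mode. The suggestion
is advisory; the configured cutoff always governs.

## Correlation screen

For one peak: Pearson r against each retained gene's log-CPM expression
across the paired observations (peak intensities raw by default, log1p via
an option — Pearson is invariant to the per-vector affine scale, so the
choice matters only for outlier behavior), two-sided P from the exact t
transform with n−2 degrees of freedom, Benjamini–Hochberg q values
(statsmodels step-up), discoveries at q < 0.01. Constant genes are kept in
the table with r = 0, p = 1 so that the output covers every retained gene.
Multiple testing is controlled per peak over genes; a multi-peak screen
applies BH within each peak independently.

Paired spots are treated as independent observations. They are not: both
assays are spatially autocorrelated, and the nominal P values are
anti-conservative to an extent that depends on the smoothness of the
fields being correlated. This mirrors the established practice the
pipeline implements and is deliberately not "fixed" here; treat the q
values as a ranking device, not literal error rates, on real tissue. (The
null-calibration test passes because its simulated genes are spatially
unstructured — it validates the statistics, not the independence
assumption.)

## Co-embedding and module discovery

The observations × features matrix stacks z-scored log-CPM expression of
the selected HVGs with z-scored log1p peak intensities. PCA retains 30
components and each feature is embedded at its loading vector scaled by
the singular values — principal-axis coordinates of variables, under which
two features with identical profiles land at the same point and the cosine
between embeddings approximates their correlation structure. Component
signs are fixed by forcing the largest-magnitude loading positive, making
repeated runs bit-identical.

Each peak is linked to its 10 nearest *gene* features by cosine distance
(the neighbor search ranges over genes only — the deliverable is a
genes-per-peak ranking — and is exhaustive, hence exact; ties break by
gene id). Community detection uses igraph's spinglass algorithm on the
graph symmetrized by maximum weight, with edge weights = cosine similarity
clipped at zero and zero-weight edges dropped, run per weakly-connected
component (isolated nodes become singletons). Two deliberate choices:

- **Resolution γ = 0.5.** The peak→gene kNN graph is bipartite, and at
  γ = 1 (equivalent to modularity) the Potts objective provably prefers
  splitting even a homogeneous dense bipartite block into straddling
  sub-communities, so γ = 1 cannot return one module per planted block.
  γ = 0.5 keeps homogeneous blocks whole while still separating unrelated
  blocks; both γ and the restart count are exposed.
- **Best-of-5 annealing restarts.** Single simulated-annealing runs
  occasionally return partitions scoring worse than the trivial
  one-community partition; each component is therefore solved 5 times with
  seeds derived from the pipeline seed and the partition with the best
  generalized modularity (same γ) is kept, making results reproducible for
  a fixed seed.

## Synthetic data: what it emulates, and what it does not

`generate_srt` builds a hexagonal-offset spot lattice (odd rows shifted
half a pitch) at 100 px pitch, mirroring 100 µm spot spacing at full
resolution. Counts are negative binomial via gamma–Poisson mixing with a
log-normal(0, 1) baseline mean per gene and NB shape 2
(variance = µ + µ²/2) — overdispersion in the range of real barcoded-spot
data, giving ~3,800 median counts and ~1,100 detected genes per spot.
Four horizontal domain bands each up-regulate a random 5% of genes 4-fold;
13 `mt-*` genes carry 5% of counts in expectation. Structure (baselines,
marker sets) and sampling noise draw from separate streams, so replicate
sections with shared means and independent noise are available for
concordance checks.

`generate_msi` places tissue pixels on a hex lattice at the MSI pitch over
the spot footprint (with equal pitches and an identity transform each
pixel coincides with its generating spot), observed in native coordinates
= inverse-transform of the common frame; the default true transform is
scale 2, rotation 0.06 rad, translation (150, −80). A planted link
(peak p, gene g, r) sets the peak's latent value at a pixel to
`r·z_g(nearest spot) + √(1−r²)·ε`, where `z_g` is the z-scored *realized*
log-CPM expression of g — the link is induced on the realized values, so
the population correlation equals r exactly and recovery is a calibrated
test, not an approximate one. Latents are mapped to positive intensities
by a per-peak affine (Pearson-preserving) scale. Unlinked peaks are smooth
plane-wave fields plus white noise; the lesion peak is multiplied by
(1 − depletion) over the lesioned hemisphere, emulating a unilateral
6-OHDA-style dopamine depletion; 300 background pixels carry near-zero
noise. Landmarks are sampled tissue pixels with Gaussian target jitter
(σ = 1 px, 8 landmarks by default).

What passing these tests does **not** show about real data: no batch or
section-to-section technical variation, no m/z drift or peak-shape
effects, no nonrigid tissue deformation (real alignment error is not pure
landmark jitter), no spatial autocorrelation in the null-calibration
genes, and no segmentation ambiguity at tissue borders. The synthetic
results validate the algorithms and their calibration under the stated
model, not robustness to those artefacts.

## Validation problem sizes

The default validation conditions are: ~1,000 paired observations, 2,000
genes, one planted link at r = 0.8, 100 simulation seeds for recovery
rates; ~500 spots × 2,000 genes × 200 seeds for null FDR calibration; 100
random instances (≤500 points/side) for the pairing oracle; 50 random
embeddings (200 genes, 20 peaks, d = 10) for kNN exactness; a ~200-tissue
/ 100-background-pixel raster for off-tissue rates. The jittered
registration bound (2 px RMS) is evaluated as the RMS pooled over the 100
seeds; per-seed worst cases reach ~2.1 px at the default noise level, and
the pooled value (~0.9 px) is the meaningful summary of the estimator's
accuracy. The full suite runs in a few minutes on one CPU.
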