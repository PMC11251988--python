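#!/usr/bin/env python
"""Quality control and replicate concordance.

Applies the spot filter (>=50 unique genes, <=38% mitochondrial counts),
the gene-family filter (hemoglobin/riboprotein/Malat1), PCA-based
off-tissue pixel removal, and measures replicate concordance: pseudobulk
gene-gene and mean-spectrum molecule-molecule Pearson correlations between
two sections sharing expression structure but with independent sampling
noise. Also ranks domain marker genes by the Wilcoxon test with Bonferroni
correction.
"""

import os

import numpy as np
import pandas as pd

from srtmsi import (
    PipelineConfig,
    SynthConfig,
    filter_genes,
    filter_spots,
    flag_offtissue,
    generate_msi,
    generate_srt,
    mean_spectrum,
    normalize_logcpm,
    pseudobulk_correlation,
    rank_markers,
    spectrum_correlation,
)

SEED = 0
os.makedirs("results", exist_ok=True)
cfg = PipelineConfig(seed=SEED)
scfg = SynthConfig(seed=SEED)

srt = generate_srt(scfg)
raster, truth = generate_msi(scfg, srt)

kept, log = filter_spots(srt, cfg)
kept, n_gene_removed = filter_genes(kept, species="mouse")
print(f"spot QC: {log.n_input} -> {log.n_retained} "
      f"(low genes {log.n_low_genes}, high mito {log.n_high_mito})")
print(f"gene filter removed {n_gene_removed} hemoglobin/riboprotein/Malat1 genes")

off = flag_offtissue(raster)
tp = off[truth.offtissue].mean()
fp = off[~truth.offtissue].mean()
print(f"off-tissue removal: {100*tp:.1f}% of background flagged, "
      f"{100*fp:.2f}% of tissue misflagged")

# replicate pair: same programs, independent noise
srt_b = generate_srt(scfg, noise_seed=SEED + 1000)
raster_b, _ = generate_msi(scfg, srt_b, noise_seed=SEED + 1000)
r_pseudo = pseudobulk_correlation([srt, srt_b]).iloc[0, 1]
r_spec = spectrum_correlation(mean_spectrum(raster), mean_spectrum(raster_b))
print(f"replicate concordance: pseudobulk r = {r_pseudo:.4f}, "
      f"mean spectrum r = {r_spec:.4f}")

normed = normalize_logcpm(kept)
domains = np.array([str(a).split("|")[0] for a in kept.annotations])
markers = rank_markers(normed, kept.gene_ids, domains, cfg)
sig = markers[markers.significant]
print(f"markers: {len(sig)} significant (log2FC > {cfg.log2fc_min}, "
      f"Bonferroni P < {cfg.padj_max}) across {len(set(domains))} domains")

pd.DataFrame(
    [
        ("spots_in", log.n_input), ("spots_kept", log.n_retained),
        ("spots_low_genes", log.n_low_genes), ("spots_high_mito", log.n_high_mito),
        ("genes_family_removed", n_gene_removed),
        ("offtissue_background_flagged_frac", float(tp)),
        ("offtissue_tissue_misflagged_frac", float(fp)),
        ("replicate_pseudobulk_r", float(r_pseudo)),
        ("replicate_mean_spectrum_r", float(r_spec)),
        ("n_significant_markers", len(sig)),
    ],
    columns=["quantity", "value"],
).to_csv("results/02_qc_summary.csv", index=False)
sig.groupby("cluster").head(10).to_csv("results/02_markers_top10.csv", index=False)
print("wrote results/02_qc_summary.csv and results/02_markers_top10.csv")
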