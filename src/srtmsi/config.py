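"""Pipeline configuration: every named threshold of the workflow in one place.

Defaults follow the published workflow this package implements: spots with
fewer than 50 unique genes or more than 38% mitochondrial counts are removed;
cross-modality pairing searches k=5 nearest spots per MSI pixel and discards
pairs farther than 35 pixels; metabolite-gene correlations are thresholded at
FDR < 0.01; co-embedding uses the top 2,000 highly variable genes and 30
principal components with ten gene neighbors per peak; markers require
log2 fold change > 0.25 at Bonferroni-adjusted P < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass
class PipelineConfig:
    min_genes_per_spot: int = 50
    max_mito_frac: float = 0.38
    knn_k: int = 5
    max_pair_dist_px: float = 35.0
    fdr_threshold: float = 0.01
    n_hvg: int = 2000
    n_pcs: int = 30
    knn_peaks: int = 10
    log2fc_min: float = 0.25
    padj_max: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            "min_genes_per_spot", "knn_k", "max_pair_dist_px", "fdr_threshold",
            "n_hvg", "n_pcs", "knn_peaks", "log2fc_min", "padj_max",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0.0 < self.max_mito_frac < 1.0:
            raise ValueError(f"max_mito_frac must lie in (0, 1), got {self.max_mito_frac}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
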