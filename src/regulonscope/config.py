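"""Run configuration: the handful of thresholds the whole pipeline shares.

Defaults follow standard practice for bacterial ChIP-exo / RNA-seq regulon
studies: peaks below a signal-to-noise ratio of 1.5 are discarded, with the
noise level set at the boundary of the top 5% of nonzero position signals;
differentially expressed genes require |log2 fold change| > 1.0 at p < 0.05;
motifs are learned at a fixed width of 20 bp from site sequences extended by
20 bp on each side.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Shared thresholds and knobs for every pipeline stage.

    Parameters
    ----------
    sn_threshold : float
        Minimum signal-to-noise ratio for a peak to be kept (strict: peaks
        with S/N < ``sn_threshold`` are removed).
    noise_top_fraction : float
        Fraction of nonzero combined-strand position signals defining the
        noise level (the smallest value among the top fraction).
    lfc_threshold : float
        log2 fold-change threshold for differential expression (strict >).
    p_threshold : float
        p-value threshold for differential expression (strict <).
    motif_width : int
        Fixed motif width in bp for EM motif discovery.
    site_extension : int
        bp added on each side of a binding site before motif discovery.
    promoter_window : int
        bp upstream of a transcriptional unit scanned for binding sites.
    merge_max_dist : int
        Maximum summit distance (bp) for merging replicate peaks.
    pseudo_fpkm : float
        Pseudo-count (FPKM units) added before log2 fold-change computation.
    od_threshold : float
        OD600 below which a culture is considered not growing (MIC calls).
    allow_n : bool
        Map ``N`` bases to random bases on genome read instead of erroring.
    seed : int
        Base seed for stochastic stages.
    """

    sn_threshold: float = 1.5
    noise_top_fraction: float = 0.05
    lfc_threshold: float = 1.0
    p_threshold: float = 0.05
    motif_width: int = 20
    site_extension: int = 20
    promoter_window: int = 300
    merge_max_dist: int = 20
    pseudo_fpkm: float = 0.5
    od_threshold: float = 0.1
    allow_n: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sn_threshold", "lfc_threshold", "p_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("noise_top_fraction",):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        for name in ("motif_width", "site_extension", "promoter_window", "merge_max_dist"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.motif_width < 1:
            raise ValueError("motif_width must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
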