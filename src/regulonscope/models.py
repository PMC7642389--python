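"""Domain types shared across the pipeline.

All internal coordinates are 0-based half-open; file readers/writers convert
to the on-disk convention at the boundary (GFF 1-based inclusive, bedGraph
0-based half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DNA_ALPHABET = frozenset("ACGT")
BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """A single contig with a validated A/C/G/T sequence."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            pos = next(i for i, b in enumerate(self.sequence) if b in bad)
            raise ValueError(
                f"non-DNA character {self.sequence[pos]!r} at position {pos}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneFeature:
    """A gene on the genome. ``start``/``end`` are 0-based half-open."""

    gene_id: str
    start: int
    end: int
    strand: str
    function_class: str = "other"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad gene interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptionalUnit:
    """An operon: contiguous co-transcribed genes sharing one promoter.

    Operon structure is an *input* (carried in annotation), never inferred.
    """

    tu_id: str
    gene_ids: list[str]
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.gene_ids:
            raise ValueError(f"TU {self.tu_id} has no genes")

    def promoter_interval(self, window: int, genome_length: int) -> tuple[int, int]:
        """Strand-aware window upstream of the first gene, clipped to genome."""
        if self.strand == "+":
            return max(0, self.start - window), self.start
        return self.end, min(genome_length, self.end + window)


@dataclass
class StrandedCoverage:
    """Per-position 5'-end read counts on each strand (ChIP-exo signal)."""

    genome_name: str
    plus: np.ndarray
    minus: np.ndarray

    def __post_init__(self) -> None:
        self.plus = np.asarray(self.plus, dtype=np.int64)
        self.minus = np.asarray(self.minus, dtype=np.int64)
        if self.plus.shape != self.minus.shape:
            raise ValueError("plus/minus tracks differ in length")
        if (self.plus < 0).any() or (self.minus < 0).any():
            raise ValueError("negative counts in coverage")

    @property
    def length(self) -> int:
        return int(self.plus.size)

    def combined(self) -> np.ndarray:
        return self.plus + self.minus


@dataclass
class Peak:
    """A called binding site: strand-paired summit plus bookkeeping."""

    peak_id: str
    start: int
    end: int
    summit: int
    signal: float
    sn_ratio: float
    location_class: str | None = None  # intragenic | intergenic
    nearest_gene: str | None = None
    replicate_support: int = 1

    def __post_init__(self) -> None:
        if not self.start <= self.summit < self.end:
            raise ValueError(
                f"summit {self.summit} outside [{self.start}, {self.end})"
            )


@dataclass
class PWM:
    """Position weight matrix: columns are positions, rows A/C/G/T probabilities."""

    probs: np.ndarray  # shape (4, width)
    n_sites: int = 0
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValueError("PWM probs must have shape (4, width)")
        colsums = self.probs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")

    @property
    def width(self) -> int:
        return int(self.probs.shape[1])

    def reverse_complement(self) -> "PWM":
        # complement = reverse row order (A<->T, C<->G), then reverse columns
        return PWM(
            probs=self.probs[::-1, ::-1].copy(),
            n_sites=self.n_sites,
            background=self.background[::-1].copy(),
        )


@dataclass
class MotifReport:
    """Case-coded consensus plus per-position information content."""

    consensus: str
    ic: np.ndarray  # bits per position
    palindrome_distance: float

    def __post_init__(self) -> None:
        self.ic = np.asarray(self.ic, dtype=float)
        if len(self.consensus) != self.ic.size:
            raise ValueError("consensus length != IC length")


@dataclass
class PlantedSite:
    """Ground-truth binding site written into a synthetic genome."""

    center: int
    strand: str
    motif_instance: str
    occupancy: float
    location_class: str = "intergenic"
    target_tu: str | None = None


@dataclass
class RegulonTruth:
    """Planted regulatory effect for one TU (ground truth for recovery tests).

    ``planted_log2fc`` is the expression effect of deleting the TF
    (ΔTF vs wild type); ``condition_effect`` is the effect of acid exposure.
    """

    tu_id: str
    mode: str  # activated_by_TF | repressed_by_TF | none
    planted_log2fc: float = 0.0
    condition_effect: float = 0.0
    bound: bool = False

    def __post_init__(self) -> None:
        if self.mode == "none" and self.planted_log2fc != 0.0:
            raise ValueError("mode 'none' requires planted_log2fc == 0")


@dataclass
class CountDesign:
    """2 strains x 2 media x n replicates RNA-seq design."""

    strains: tuple[str, str] = ("WT", "dTF")
    media: tuple[str, str] = ("plain", "acid")
    replicates: int = 2
    mean_depth: float = 2e6
    dispersion: float = 0.01

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates (biological duplicate)")

    def samples(self) -> list[tuple[str, str, int]]:
        return [
            (s, m, r + 1)
            for s in self.strains
            for m in self.media
            for r in range(self.replicates)
        ]


@dataclass
class RegulonEntry:
    """One TU in the reconstructed regulon."""

    tu_id: str
    gene_ids: list[str]
    bound: bool
    de_response: float  # log2FC, ΔTF vs WT
    mode: str  # activated_by_TF | repressed_by_TF | bound_only | indirect | none
    peak_ids: list[str] = field(default_factory=list)
    de_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.bound and self.mode not in ("indirect", "none"):
            raise ValueError("unbound TU can only be 'indirect' or 'none'")
        if self.mode == "repressed_by_TF" and self.de_response <= 0:
            raise ValueError("repressed_by_TF requires de_response > 0")
        if self.mode == "activated_by_TF" and self.de_response >= 0:
            raise ValueError("activated_by_TF requires de_response < 0")


CANDIDATE_FLAGS = (
    "promoter_divergence",
    "high_fold_change",
    "acid_resistance_regulator",
    "membrane_synthesis",
    "unknown_function",
)


@dataclass
class CandidateRecord:
    """One operon in the five-category prioritization cascade."""

    operon_id: str
    gene_ids: list[str]
    flags: dict[str, bool]
    selected: bool = False
    rationale: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.flags) - set(CANDIDATE_FLAGS)
        if unknown:
            raise ValueError(f"unknown candidate flags: {sorted(unknown)}")
        for f in CANDIDATE_FLAGS:
            self.flags.setdefault(f, False)

    @property
    def n_flags(self) -> int:
        return sum(bool(v) for v in self.flags.values())


@dataclass
class MICResult:
    """Minimal inhibitory concentration call from an OD-vs-concentration table."""

    mic_mM: float | None  # None => growth at every tested concentration
    above_range: bool
    warnings: list[str] = field(default_factory=list)

    @property
    def as_float(self) -> float:
        return float("inf") if self.above_range else float(self.mic_mM)
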