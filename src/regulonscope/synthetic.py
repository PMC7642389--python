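"""Synthetic genomes, planted binding sites, ChIP-exo coverage and RNA-seq counts.

The generator emulates the data shapes of a bacterial TF regulon study:

* a toy genome with non-overlapping genes grouped into operons (TUs);
* palindromic binding-site instances sampled from a PWM and written into the
  sequence, split between intergenic (promoter-proximal) and intragenic
  locations;
* stranded 5'-end ChIP-exo coverage: for each site, Poisson read spikes at
  ``center - border_offset`` on the plus strand and ``center + border_offset``
  on the minus strand (the exonuclease border geometry), over a uniform
  Poisson background;
* a 2-strain x 2-media x n-replicate negative-binomial count matrix where all
  genes of a TU share the planted TF-deletion and acid-condition effects.

The default scenario plants 33 sites (21 intergenic / 12 intragenic) on a
100 kb genome with 60 genes, includes two ~10-fold TF-repressed operons and
one ~2.2-fold one, and uses biological duplicates throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .models import (
    BASES,
    CountDesign,
    GeneFeature,
    Genome,
    PlantedSite,
    PWM,
    RegulonTruth,
    StrandedCoverage,
    TranscriptionalUnit,
    revcomp,
)
from . import io_formats


# ---------------------------------------------------------------------------
# Planted motif
# ---------------------------------------------------------------------------

def build_palindromic_pwm(
    width: int = 20,
    core_prob: float = 0.9,
    flank_prob: float = 0.55,
    n_flank: int = 3,
    half_consensus: str = "AATTTGTATG",
) -> PWM:
    """A palindromic PWM: half-site consensus followed by its reverse complement.

    ``n_flank`` positions at each end get probability ``flank_prob`` (low
    information, lower-case in the consensus); the core gets ``core_prob``.
    The construction is exactly reverse-complement symmetric.
    """
    if 2 * len(half_consensus) != width:
        raise ValueError("half_consensus must be width/2 long")
    consensus = half_consensus + revcomp(half_consensus)
    probs = np.zeros((4, width))
    for j, base in enumerate(consensus):
        p = flank_prob if (j < n_flank or j >= width - n_flank) else core_prob
        probs[:, j] = (1.0 - p) / 3.0
        probs[BASES.index(base), j] = p
    return PWM(probs=probs)


def sample_from_pwm(pwm: PWM, rng: np.random.Generator) -> str:
    idx = [rng.choice(4, p=pwm.probs[:, j]) for j in range(pwm.width)]
    return "".join(BASES[i] for i in idx)


# ---------------------------------------------------------------------------
# Genome + annotation
# ---------------------------------------------------------------------------

def generate_genome(
    length: int,
    gc: float,
    n_genes: int,
    operon_sizes: tuple[int, ...] = (1, 2, 3),
    operon_size_probs: tuple[float, ...] | None = None,
    gene_length_range: tuple[int, int] = (600, 1200),
    intra_operon_gap: int = 20,
    min_spacing: int = 150,
    seed: int | np.random.Generator = 0,
    name: str = "synthgenome",
) -> tuple[Genome, list[GeneFeature], list[TranscriptionalUnit]]:
    """Random genome with non-overlapping genes packed into operons.

    Operon sizes are drawn from ``operon_sizes`` (uniformly unless
    ``operon_size_probs`` given) until ``n_genes`` genes are placed; inter-TU
    gaps of at least ``min_spacing`` bp are randomized so intergenic space is
    spread along the genome. Deterministic under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")

    # draw operon sizes
    sizes: list[int] = []
    while sum(sizes) < n_genes:
        sizes.append(int(rng.choice(operon_sizes, p=operon_size_probs)))
    sizes[-1] -= sum(sizes) - n_genes
    if sizes[-1] == 0:
        sizes.pop()

    gene_lengths = rng.integers(gene_length_range[0], gene_length_range[1] + 1, n_genes)
    total_genic = int(gene_lengths.sum()) + intra_operon_gap * (n_genes - len(sizes))
    n_gaps = len(sizes) + 1
    slack = length - total_genic - min_spacing * n_gaps
    if slack < 0:
        raise ValueError(
            f"cannot pack {n_genes} genes into {length} bp with spacing {min_spacing}"
        )
    # randomized inter-TU gaps summing to the available slack
    cuts = np.sort(rng.integers(0, slack + 1, n_gaps - 1))
    extra = np.diff(np.concatenate([[0], cuts, [slack]]))
    gaps = min_spacing + extra

    seq = rng.choice(
        list("ACGT"), size=length, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    )
    genes: list[GeneFeature] = []
    tus: list[TranscriptionalUnit] = []
    pos = 0
    gi = 0
    for ti, size in enumerate(sizes):
        pos += int(gaps[ti])
        strand = "+" if rng.random() < 0.5 else "-"
        members: list[GeneFeature] = []
        for k in range(size):
            glen = int(gene_lengths[gi])
            gene = GeneFeature(
                gene_id=f"g{gi + 1:03d}",
                start=pos,
                end=pos + glen,
                strand=strand,
                function_class="other",
            )
            members.append(gene)
            genes.append(gene)
            pos += glen
            if k < size - 1:
                pos += intra_operon_gap
            gi += 1
        ordered = members if strand == "+" else members[::-1]
        tus.append(
            TranscriptionalUnit(
                tu_id=f"TU{ti + 1:03d}",
                gene_ids=[g.gene_id for g in ordered],
                strand=strand,
                start=members[0].start,
                end=members[-1].end,
            )
        )
    genome = Genome(name=name, sequence="".join(seq))
    return genome, genes, tus


# ---------------------------------------------------------------------------
# Site planting
# ---------------------------------------------------------------------------

def _intergenic_mask(length: int, genes: list[GeneFeature]) -> np.ndarray:
    mask = np.ones(length, dtype=bool)
    for g in genes:
        mask[g.start : g.end] = False
    return mask


def plant_sites(
    genome: Genome,
    genes: list[GeneFeature],
    tus: list[TranscriptionalUnit],
    pwm: PWM,
    n_sites: int,
    fraction_intergenic: float,
    seed: int | np.random.Generator = 0,
    promoter_offset_range: tuple[int, int] = (40, 200),
    occupancy_range: tuple[float, float] = (0.7, 1.3),
) -> tuple[Genome, list[PlantedSite]]:
    """Write ``n_sites`` motif instances into the genome sequence.

    Intergenic sites are placed upstream of TU starts (within
    ``promoter_offset_range`` bp of the first gene, strand-aware) while
    intergenic space allows — TF sites sit in promoters — falling back to
    arbitrary intergenic positions; intragenic sites go inside gene bodies.
    The intergenic/intragenic split is exact. Sites never overlap each other.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = pwm.width
    n_inter = int(round(fraction_intergenic * n_sites))
    n_intra = n_sites - n_inter
    free = _intergenic_mask(genome.length, genes)
    occupied = np.zeros(genome.length, dtype=bool)

    def window_ok(start: int, need_intergenic: bool) -> bool:
        if start < 0 or start + w > genome.length:
            return False
        if occupied[start : start + w].any():
            return False
        region = free[start : start + w]
        return region.all() if need_intergenic else not region.any()

    sites: list[PlantedSite] = []
    seq = list(genome.sequence)

    def place(start: int, location_class: str, target_tu: str | None) -> None:
        instance = sample_from_pwm(pwm, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        written = instance if strand == "+" else revcomp(instance)
        seq[start : start + w] = written
        occupied[start : start + w] = True
        sites.append(
            PlantedSite(
                center=start + w // 2,
                strand=strand,
                motif_instance=instance,
                occupancy=float(rng.uniform(*occupancy_range)),
                location_class=location_class,
                target_tu=target_tu,
            )
        )

    # intergenic sites: promoter-proximal first
    tu_order = list(tus)
    rng.shuffle(tu_order)
    for tu in tu_order:
        if len([s for s in sites if s.location_class == "intergenic"]) >= n_inter:
            break
        for _ in range(20):
            off = int(rng.integers(*promoter_offset_range))
            if tu.strand == "+":
                start = tu.start - off - w
            else:
                start = tu.end + off
            if window_ok(start, need_intergenic=True):
                place(start, "intergenic", tu.tu_id)
                break
    # fall back to arbitrary intergenic space
    candidates = np.flatnonzero(free & ~occupied)
    rng.shuffle(candidates)
    ci = 0
    while len([s for s in sites if s.location_class == "intergenic"]) < n_inter:
        if ci >= candidates.size:
            raise ValueError("not enough intergenic space to plant sites")
        start = int(candidates[ci])
        ci += 1
        if window_ok(start, need_intergenic=True):
            place(start, "intergenic", None)

    # intragenic sites
    gene_order = list(genes)
    rng.shuffle(gene_order)
    placed_intra = 0
    for g in gene_order:
        if placed_intra >= n_intra:
            break
        if g.length < w + 2:
            continue
        for _ in range(20):
            start = int(rng.integers(g.start, g.end - w + 1))
            if window_ok(start, need_intergenic=False):
                place(start, "intragenic", None)
                placed_intra += 1
                break
    if placed_intra < n_intra:
        raise ValueError("not enough intragenic space to plant sites")

    return Genome(name=genome.name, sequence="".join(seq)), sites


# ---------------------------------------------------------------------------
# ChIP-exo coverage
# ---------------------------------------------------------------------------

def simulate_chipexo(
    genome_length: int,
    sites: list[PlantedSite],
    border_offset: int = 10,
    reads_per_occupancy: float = 50.0,
    background_rate: float = 0.02,
    n_replicates: int = 2,
    seed: int | np.random.Generator = 0,
    genome_name: str = "synthgenome",
) -> list[StrandedCoverage]:
    """Stranded 5'-end coverage: exo border spikes over Poisson background.

    Each site contributes Poisson(occupancy * reads_per_occupancy / 2) reads
    at ``center - border_offset`` on the plus strand and the mirror position
    on the minus strand; the background is uniform Poisson at
    ``background_rate / 2`` per strand per position. Replicates are
    independent draws.
    """
    if border_offset <= 0:
        raise ValueError("border_offset must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reps = []
    for _ in range(n_replicates):
        plus = rng.poisson(background_rate / 2.0, genome_length)
        minus = rng.poisson(background_rate / 2.0, genome_length)
        for s in sites:
            lam = s.occupancy * reads_per_occupancy / 2.0
            p_pos = s.center - border_offset
            m_pos = s.center + border_offset
            if 0 <= p_pos < genome_length:
                plus[p_pos] += rng.poisson(lam)
            if 0 <= m_pos < genome_length:
                minus[m_pos] += rng.poisson(lam)
        reps.append(StrandedCoverage(genome_name=genome_name, plus=plus, minus=minus))
    return reps


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

def simulate_counts(
    genes: list[GeneFeature],
    tus: list[TranscriptionalUnit],
    truth: list[RegulonTruth],
    design: CountDesign,
    seed: int | np.random.Generator = 0,
    baseline_sigma: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix with TU-shared planted effects.

    Per-gene baseline abundances are log-normal; each sample's expected
    counts are baseline * 2^(planted_log2fc if ΔTF) * 2^(condition_effect if
    acid), scaled so the wild-type/plain library totals ``mean_depth``.
    Returns (counts gene x sample, sample table).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tu_ids = {tu.tu_id for tu in tus}
    for t in truth:
        if t.tu_id not in tu_ids:
            raise ValueError(f"truth refers to unknown TU {t.tu_id}")
    effects = {t.tu_id: t for t in truth}
    gene_tu = {}
    for tu in tus:
        for gid in tu.gene_ids:
            gene_tu[gid] = tu.tu_id

    gene_ids = [g.gene_id for g in genes]
    base = np.exp(rng.normal(0.0, baseline_sigma, len(genes)))
    base *= design.mean_depth / base.sum()

    lfc = np.zeros(len(genes))
    cond = np.zeros(len(genes))
    for i, gid in enumerate(gene_ids):
        t = effects.get(gene_tu.get(gid))
        if t is not None:
            lfc[i] = t.planted_log2fc
            cond[i] = t.condition_effect

    samples = design.samples()
    names = [f"{s}_{m}_r{r}" for s, m, r in samples]
    counts = np.zeros((len(genes), len(samples)), dtype=np.int64)
    for j, (strain, media, _rep) in enumerate(samples):
        mu = base * 2.0 ** (
            lfc * (strain != design.strains[0]) + cond * (media != design.media[0])
        )
        if design.dispersion <= 1e-8:
            counts[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / design.dispersion
            counts[:, j] = rng.negative_binomial(r, r / (r + mu))
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=names)
    sample_df = pd.DataFrame(
        [{"sample": n, "strain": s, "media": m, "replicate": r} for n, (s, m, r) in zip(names, samples)]
    )
    return counts_df, sample_df


# ---------------------------------------------------------------------------
# Scenario: the full study-shaped dataset
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """Parameters of a full synthetic study.

    Defaults mirror the shape of the motivating regulon study: a 100 kb
    genome with 60 genes in 1-3-gene operons, 33 planted palindromic sites
    (21 intergenic / 12 intragenic), ChIP-exo in biological duplicate, a
    2-strain x 2-media x 2-replicate RNA-seq design, two ~10-fold
    TF-repressed operons (log2FC 3.32) and one ~2.2-fold one (log2FC 1.14),
    plus activated, bound-only and indirect TUs.
    """

    genome_length: int = 100_000
    gc: float = 0.5
    n_genes: int = 60
    n_sites: int = 33
    n_intergenic: int = 21
    border_offset: int = 10
    reads_per_occupancy: float = 50.0
    background_rate: float = 0.02
    n_chip_replicates: int = 2
    replicates: int = 2
    mean_depth: float = 2e6
    dispersion: float = 0.01
    motif_width: int = 20
    # planted regulon composition (TUs with a promoter-proximal site)
    strong_repressed_log2fc: float = 3.32  # ~10-fold up on TF deletion
    mild_repressed_log2fc: float = 1.14  # ~2.2-fold
    n_strong_repressed: int = 2
    n_mild_repressed: int = 1
    n_repressed: int = 3  # additional, +2.0
    n_activated: int = 4  # -2.0
    n_indirect: int = 4  # unbound TUs with +/-2.0
    n_acid_responsive: int = 6  # TUs given a +/-1.5 acid condition effect
    other_log2fc: float = 2.0
    acid_effect: float = 1.5
    truth_promoter_window: int = 300  # window defining ground-truth "bound"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class SyntheticDataset:
    """Everything one simulated study produces, with ground truth attached."""

    genome: Genome
    genes: list[GeneFeature]
    tus: list[TranscriptionalUnit]
    pwm: PWM
    sites: list[PlantedSite]
    coverage: list[StrandedCoverage]
    counts: pd.DataFrame
    samples: pd.DataFrame
    truth: list[RegulonTruth]
    scenario: Scenario


def simulate_scenario(scenario: Scenario | None = None, seed: int = 0) -> SyntheticDataset:
    """Generate a complete study-shaped dataset under one seed.

    Bound TUs (those that received a promoter-proximal planted site) are
    assigned repressed/activated/bound-only roles; some unbound TUs get
    indirect effects; acid-condition effects are sprinkled independently.
    """
    sc = scenario or Scenario()
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(5)]

    genome, genes, tus = generate_genome(
        length=sc.genome_length, gc=sc.gc, n_genes=sc.n_genes, seed=rngs[0]
    )
    pwm = build_palindromic_pwm(width=sc.motif_width)
    genome, sites = plant_sites(
        genome,
        genes,
        tus,
        pwm,
        n_sites=sc.n_sites,
        fraction_intergenic=sc.n_intergenic / sc.n_sites,
        seed=rngs[1],
    )
    coverage = simulate_chipexo(
        genome.length,
        sites,
        border_offset=sc.border_offset,
        reads_per_occupancy=sc.reads_per_occupancy,
        background_rate=sc.background_rate,
        n_replicates=sc.n_chip_replicates,
        seed=rngs[2],
        genome_name=genome.name,
    )

    rng = rngs[3]
    # ground-truth binding is geometric: a TU is bound iff a planted site
    # center sits in its body or promoter window (the same rule integration
    # applies), so divergent promoters sharing a site are both bound
    win = sc.truth_promoter_window
    bound_set: set[str] = set()
    for tu in tus:
        lo = tu.start - win if tu.strand == "+" else tu.start
        hi = tu.end if tu.strand == "+" else tu.end + win
        if any(lo <= s.center < hi for s in sites):
            bound_set.add(tu.tu_id)
    bound_tus = [s.target_tu for s in sites if s.target_tu is not None]
    bound_tus += sorted(bound_set - set(bound_tus))
    unbound_tus = [tu.tu_id for tu in tus if tu.tu_id not in bound_set]
    rng.shuffle(unbound_tus)

    truth: list[RegulonTruth] = []
    roles: list[tuple[str, float]] = (
        [("repressed_by_TF", sc.strong_repressed_log2fc)] * sc.n_strong_repressed
        + [("repressed_by_TF", sc.mild_repressed_log2fc)] * sc.n_mild_repressed
        + [("repressed_by_TF", sc.other_log2fc)] * sc.n_repressed
        + [("activated_by_TF", -sc.other_log2fc)] * sc.n_activated
    )
    assigned: set[str] = set()
    for tu_id, (mode, lfc) in zip(bound_tus, roles):
        truth.append(RegulonTruth(tu_id=tu_id, mode=mode, planted_log2fc=lfc, bound=True))
        assigned.add(tu_id)
    for tu_id in bound_tus:
        if tu_id not in assigned:
            truth.append(RegulonTruth(tu_id=tu_id, mode="none", bound=True))
            assigned.add(tu_id)
    for tu_id in unbound_tus[: sc.n_indirect]:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        mode = "repressed_by_TF" if sign > 0 else "activated_by_TF"
        truth.append(
            RegulonTruth(tu_id=tu_id, mode=mode, planted_log2fc=sign * sc.other_log2fc, bound=False)
        )
        assigned.add(tu_id)
    for tu_id in unbound_tus[sc.n_indirect :]:
        truth.append(RegulonTruth(tu_id=tu_id, mode="none", bound=False))

    acid_pool = [t for t in truth]
    rng.shuffle(acid_pool)
    for t in acid_pool[: sc.n_acid_responsive]:
        t.condition_effect = sc.acid_effect if rng.random() < 0.5 else -sc.acid_effect

    # function classes for the prioritization cascade: strongly TF-repressed
    # operons are function-unknown (putative transporters), the mild one is an
    # acid-resistance regulator, one activated TU makes membrane components
    by_id = {g.gene_id: g for g in genes}
    tu_by_id = {tu.tu_id: tu for tu in tus}

    def _set_class(tu_id: str, fclass: str) -> None:
        for gid in tu_by_id[tu_id].gene_ids:
            by_id[gid].function_class = fclass

    strong = [t.tu_id for t in truth if t.planted_log2fc == sc.strong_repressed_log2fc]
    mild = [t.tu_id for t in truth if t.planted_log2fc == sc.mild_repressed_log2fc]
    activated = [t.tu_id for t in truth if t.mode == "activated_by_TF" and t.bound]
    for tu_id in strong:
        _set_class(tu_id, "unknown")
    for tu_id in mild:
        _set_class(tu_id, "acid_resistance")
    for tu_id in activated[:1]:
        _set_class(tu_id, "membrane_synthesis")

    design = CountDesign(
        replicates=sc.replicates, mean_depth=sc.mean_depth, dispersion=sc.dispersion
    )
    counts, samples = simulate_counts(genes, tus, truth, design, seed=rngs[4])

    return SyntheticDataset(
        genome=genome,
        genes=genes,
        tus=tus,
        pwm=pwm,
        sites=sites,
        coverage=coverage,
        counts=counts,
        samples=samples,
        truth=truth,
        scenario=sc,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated dataset to disk in the pipeline's on-disk formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.gff",
        "counts": outdir / "counts.tsv",
        "sites": outdir / "truth_sites.tsv",
        "truth": outdir / "truth_regulon.tsv",
    }
    io_formats.write_genome(ds.genome, paths["genome"])
    io_formats.write_annotation(ds.genes, ds.tus, paths["annotation"], seqid=ds.genome.name)
    io_formats.write_counts(ds.counts, paths["counts"])
    io_formats.write_sites(ds.sites, paths["sites"])
    io_formats.write_truth(ds.truth, paths["truth"])
    for i, cov in enumerate(ds.coverage, start=1):
        pp = outdir / f"chipexo_rep{i}_plus.bedGraph"
        mp = outdir / f"chipexo_rep{i}_minus.bedGraph"
        io_formats.write_coverage(cov, pp, mp)
        paths[f"chipexo_rep{i}_plus"] = pp
        paths[f"chipexo_rep{i}_minus"] = mp
    return paths
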