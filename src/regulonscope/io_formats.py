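"""Readers and writers for every on-disk format the pipeline touches.

Conventions
-----------
* Internal coordinates are 0-based half-open everywhere.
* GFF3 on disk is 1-based inclusive; bedGraph/BED are 0-based half-open.
* Operon (TU) membership travels in a custom ``tu_id`` GFF attribute; a gene
  without one becomes a singleton TU.
* Stranded ChIP-exo coverage is two bedGraph tracks (plus / minus), the
  standard representation for 5'-end exo signal.

Every writer round-trips losslessly with its paired reader.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

from .models import (
    DNA_ALPHABET,
    GeneFeature,
    Genome,
    Peak,
    PlantedSite,
    RegulonTruth,
    StrandedCoverage,
    TranscriptionalUnit,
)

log = logging.getLogger("regulonscope.io")

FUNCTION_CLASSES = ("known", "unknown", "membrane_synthesis", "acid_resistance", "other")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome(path: str | Path, allow_n: bool = False, seed: int = 0) -> Genome:
    """Read a genome from FASTA (first record), upper-cased and validated.

    ``N`` bases raise by default; with ``allow_n=True`` they are replaced by
    random bases (synthetic-data convenience), seeded for reproducibility.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty or non-FASTA file: {path}")
    rec = records[0]
    seq = str(rec.seq).upper()
    if "N" in seq:
        if not allow_n:
            pos = seq.index("N")
            raise ValueError(f"non-ACGT character 'N' at position {pos} in {path}")
        rng = np.random.default_rng(seed)
        arr = np.array(list(seq))
        n_mask = arr == "N"
        arr[n_mask] = rng.choice(list("ACGT"), size=int(n_mask.sum()))
        seq = "".join(arr)
    bad = set(seq) - DNA_ALPHABET
    if bad:
        pos = next(i for i, b in enumerate(seq) if b in bad)
        raise ValueError(f"non-DNA character {seq[pos]!r} at position {pos} in {path}")
    return Genome(name=rec.id, sequence=seq)


def write_genome(genome: Genome, path: str | Path, line_width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.name}\n")
        for i in range(0, genome.length, line_width):
            fh.write(genome.sequence[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 annotation (genes + TUs via tu_id attribute)
# ---------------------------------------------------------------------------

def read_annotation(
    path: str | Path,
) -> tuple[list[GeneFeature], list[TranscriptionalUnit]]:
    """Parse gene rows from GFF3 and assemble transcriptional units.

    TU membership comes from the ``tu_id`` attribute; genes lacking it get a
    singleton TU named after the gene. Raises on TUs with mixed strands or
    with a foreign gene interleaved between members.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneFeature] = []
    tu_members: dict[str, list[GeneFeature]] = {}
    order: dict[str, int] = {}
    for f in db.features_of_type("gene", order_by="start"):
        gid = f.attributes.get("ID", [f.id])[0]
        fclass = f.attributes.get("function_class", ["other"])[0]
        gene = GeneFeature(
            gene_id=gid,
            start=f.start - 1,  # GFF 1-based inclusive -> 0-based half-open
            end=f.end,
            strand=f.strand,
            function_class=fclass,
        )
        genes.append(gene)
        tu_id = f.attributes.get("tu_id", [None])[0]
        if tu_id is None:
            tu_id = f"TU_{gid}"
            log.debug("gene %s has no tu_id; singleton TU %s", gid, tu_id)
        tu_members.setdefault(tu_id, []).append(gene)
        order.setdefault(tu_id, len(order))

    genes.sort(key=lambda g: g.start)
    tus = []
    for tu_id in sorted(tu_members, key=order.get):
        members = sorted(tu_members[tu_id], key=lambda g: g.start)
        strands = {g.strand for g in members}
        if len(strands) > 1:
            raise ValueError(f"TU {tu_id} has genes on both strands")
        strand = strands.pop()
        start, end = members[0].start, members[-1].end
        member_ids = {g.gene_id for g in members}
        for g in genes:
            if g.gene_id not in member_ids and g.start >= start and g.end <= end:
                raise ValueError(
                    f"TU {tu_id} is not contiguous: gene {g.gene_id} interleaved"
                )
        # order members 5'->3'
        if strand == "-":
            members = members[::-1]
        tus.append(
            TranscriptionalUnit(
                tu_id=tu_id,
                gene_ids=[g.gene_id for g in members],
                strand=strand,
                start=start,
                end=end,
            )
        )
    return genes, tus


def write_annotation(
    genes: list[GeneFeature],
    tus: list[TranscriptionalUnit],
    path: str | Path,
    seqid: str = "chr",
) -> None:
    gene_tu = {}
    for tu in tus:
        for gid in tu.gene_ids:
            gene_tu[gid] = tu.tu_id
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: g.start):
            attrs = f"ID={g.gene_id};function_class={g.function_class}"
            if g.gene_id in gene_tu:
                attrs += f";tu_id={gene_tu[g.gene_id]}"
            fh.write(
                "\t".join(
                    [
                        seqid,
                        "regulonscope",
                        "gene",
                        str(g.start + 1),  # back to 1-based inclusive
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# bedGraph stranded coverage
# ---------------------------------------------------------------------------

def _write_bedgraph(values: np.ndarray, name: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        i, n = 0, values.size
        while i < n:
            j = i
            while j < n and values[j] == values[i]:
                j += 1
            if values[i] != 0:
                fh.write(f"{name}\t{i}\t{j}\t{int(values[i])}\n")
            i = j


def write_coverage(cov: StrandedCoverage, plus_path: str | Path, minus_path: str | Path) -> None:
    """Write coverage as two bedGraph tracks (0-based half-open, zeros omitted)."""
    _write_bedgraph(cov.plus, cov.genome_name, plus_path)
    _write_bedgraph(cov.minus, cov.genome_name, minus_path)


def _read_bedgraph(path: str | Path, length: int) -> tuple[str, np.ndarray]:
    values = np.zeros(length, dtype=np.int64)
    name = "chr"
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            name, s, e, v = line.split("\t")
            values[int(s) : int(e)] = int(v)
    return name, values


def read_coverage(
    plus_path: str | Path, minus_path: str | Path, genome_length: int
) -> StrandedCoverage:
    name, plus = _read_bedgraph(plus_path, genome_length)
    _, minus = _read_bedgraph(minus_path, genome_length)
    return StrandedCoverage(genome_name=name, plus=plus, minus=minus)


# ---------------------------------------------------------------------------
# Peaks: BED6 + extended TSV
# ---------------------------------------------------------------------------

PEAK_COLUMNS = [
    "peak_id",
    "start",
    "end",
    "summit",
    "signal",
    "sn_ratio",
    "location_class",
    "nearest_gene",
    "replicate_support",
]


def peaks_to_frame(peaks: list[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "peak_id": p.peak_id,
                "start": p.start,
                "end": p.end,
                "summit": p.summit,
                "signal": p.signal,
                "sn_ratio": p.sn_ratio,
                "location_class": p.location_class or "",
                "nearest_gene": p.nearest_gene or "",
                "replicate_support": p.replicate_support,
            }
            for p in peaks
        ],
        columns=PEAK_COLUMNS,
    )


def write_peaks(peaks: list[Peak], tsv_path: str | Path, bed_path: str | Path | None = None,
                seqid: str = "chr") -> None:
    df = peaks_to_frame(peaks)
    df.to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for p in peaks:
                score = min(1000, int(round(p.sn_ratio * 100)))
                fh.write(f"{seqid}\t{p.start}\t{p.end}\t{p.peak_id}\t{score}\t.\n")


def read_peaks(tsv_path: str | Path) -> list[Peak]:
    df = pd.read_csv(tsv_path, sep="\t", keep_default_na=False, float_precision="round_trip")
    peaks = []
    for row in df.itertuples(index=False):
        peaks.append(
            Peak(
                peak_id=str(row.peak_id),
                start=int(row.start),
                end=int(row.end),
                summit=int(row.summit),
                signal=float(row.signal),
                sn_ratio=float(row.sn_ratio),
                location_class=str(row.location_class) or None,
                nearest_gene=str(row.nearest_gene) or None,
                replicate_support=int(row.replicate_support),
            )
        )
    return peaks


# ---------------------------------------------------------------------------
# Counts, planted sites, planted truth: plain TSV
# ---------------------------------------------------------------------------

def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def parse_sample_name(name: str) -> tuple[str, str, int]:
    """``WT_plain_r1`` -> (strain, media, replicate)."""
    strain, media, rep = name.rsplit("_", 2)
    return strain, media, int(rep.lstrip("r"))


def write_sites(sites: list[PlantedSite], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "center": s.center,
                "strand": s.strand,
                "motif_instance": s.motif_instance,
                "occupancy": s.occupancy,
                "location_class": s.location_class,
                "target_tu": s.target_tu or "",
            }
            for s in sites
        ],
        columns=["center", "strand", "motif_instance", "occupancy", "location_class", "target_tu"],
    ).to_csv(path, sep="\t", index=False)


def read_sites(path: str | Path) -> list[PlantedSite]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, float_precision="round_trip")
    return [
        PlantedSite(
            center=int(r.center),
            strand=str(r.strand),
            motif_instance=str(r.motif_instance),
            occupancy=float(r.occupancy),
            location_class=str(r.location_class),
            target_tu=str(r.target_tu) or None,
        )
        for r in df.itertuples(index=False)
    ]


def write_truth(truth: list[RegulonTruth], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "tu_id": t.tu_id,
                "mode": t.mode,
                "planted_log2fc": t.planted_log2fc,
                "condition_effect": t.condition_effect,
                "bound": int(t.bound),
            }
            for t in truth
        ],
        columns=["tu_id", "mode", "planted_log2fc", "condition_effect", "bound"],
    ).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> list[RegulonTruth]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, float_precision="round_trip")
    return [
        RegulonTruth(
            tu_id=str(r.tu_id),
            mode=str(r.mode),
            planted_log2fc=float(r.planted_log2fc),
            condition_effect=float(r.condition_effect),
            bound=bool(int(r.bound)),
        )
        for r in df.itertuples(index=False)
    ]
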