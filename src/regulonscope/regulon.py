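"""Regulon reconstruction: binding evidence x expression response per TU.

A TU is *bound* when a peak summit falls in its body or its strand-aware
promoter window (default 300 bp upstream). Combining binding with the
ΔTF-vs-WT differential expression gives the regulatory mode:

* bound + member up in the deletion strain  -> repressed_by_TF
  (removing a repressor raises expression);
* bound + member down                       -> activated_by_TF;
* bound, no significant member              -> bound_only;
* unbound + significant member              -> indirect;
* otherwise                                 -> none.

TU mode is the majority vote of its significant members; ties go to the
member with the strongest |log2FC|. Every peak is either assigned to at
least one TU (divergent promoters may share one peak) or reported orphan.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import RunConfig
from .models import Peak, RegulonEntry, TranscriptionalUnit

log = logging.getLogger("regulonscope.regulon")


def map_peaks_to_tus(
    peaks: list[Peak],
    tus: list[TranscriptionalUnit],
    promoter_window: int = 300,
    genome_length: int | None = None,
) -> tuple[dict[str, list[Peak]], list[Peak]]:
    """Assign peaks to TUs whose body or promoter window contains the summit.

    Returns (tu_id -> peaks, orphan peaks). A summit between two divergent
    promoters can be assigned to both TUs; unassigned peaks come back as
    orphans so no peak is silently dropped.
    """
    L = genome_length if genome_length is not None else max((tu.end for tu in tus), default=0) + promoter_window
    assignments: dict[str, list[Peak]] = {tu.tu_id: [] for tu in tus}
    orphans: list[Peak] = []
    for p in peaks:
        hit = False
        for tu in tus:
            if tu.strand == "+":
                lo, hi = max(0, tu.start - promoter_window), tu.end
            else:
                lo, hi = tu.start, min(L, tu.end + promoter_window)
            if lo <= p.summit < hi:
                assignments[tu.tu_id].append(p)
                hit = True
        if not hit:
            orphans.append(p)
    return assignments, orphans


def classify_regulation(
    assignments: dict[str, list[Peak]],
    de_results: pd.DataFrame,
    tus: list[TranscriptionalUnit],
    config: RunConfig | None = None,
) -> list[RegulonEntry]:
    """Label each TU with its regulatory mode from binding + ΔTF-vs-WT DE.

    ``de_results`` must be the deletion-strain vs wild-type comparison (the
    standard DE table with gene_id, log2fc, p_value, significant). Genes
    missing from the table are skipped with a warning.
    """
    cfg = config or RunConfig()
    de = de_results.set_index("gene_id")
    entries: list[RegulonEntry] = []
    for tu in tus:
        peaks = assignments.get(tu.tu_id, [])
        bound = len(peaks) > 0
        member_lfc: dict[str, float] = {}
        sig_lfc: dict[str, float] = {}
        for gid in tu.gene_ids:
            if gid not in de.index:
                log.warning("TU %s member %s missing from DE table; skipped", tu.tu_id, gid)
                continue
            row = de.loc[gid]
            member_lfc[gid] = float(row["log2fc"])
            if bool(row["significant"]):
                sig_lfc[gid] = float(row["log2fc"])

        if sig_lfc:
            strongest = max(sig_lfc, key=lambda g: abs(sig_lfc[g]))
            n_up = sum(1 for v in sig_lfc.values() if v > 0)
            n_down = sum(1 for v in sig_lfc.values() if v < 0)
            if n_up > n_down:
                direction = 1.0
            elif n_down > n_up:
                direction = -1.0
            else:
                direction = np.sign(sig_lfc[strongest])
            # representative response: strongest significant member in the
            # majority direction
            in_dir = {g: v for g, v in sig_lfc.items() if np.sign(v) == direction}
            rep_gene = max(in_dir, key=lambda g: abs(in_dir[g]))
            de_response = in_dir[rep_gene]
        else:
            de_response = float(np.mean(list(member_lfc.values()))) if member_lfc else 0.0

        if bound and sig_lfc:
            mode = "repressed_by_TF" if de_response > 0 else "activated_by_TF"
        elif bound:
            mode = "bound_only"
        elif sig_lfc:
            mode = "indirect"
        else:
            mode = "none"
        entries.append(
            RegulonEntry(
                tu_id=tu.tu_id,
                gene_ids=list(tu.gene_ids),
                bound=bound,
                de_response=de_response,
                mode=mode,
                peak_ids=[p.peak_id for p in peaks],
                de_genes=sorted(sig_lfc),
            )
        )
    return entries


def combine_de_tables(
    plain: pd.DataFrame, acid: pd.DataFrame, policy: str = "either"
) -> pd.DataFrame:
    """Merge the plain- and acid-condition ΔTF-vs-WT DE tables per gene.

    ``either``: significant if significant in either condition (the
    stronger-|log2FC| significant row represents the gene); ``both``:
    significant only if significant in both; ``plain_only`` / ``acid_only``
    pass one table through.
    """
    if policy == "plain_only":
        return plain.copy()
    if policy == "acid_only":
        return acid.copy()
    if policy not in ("either", "both"):
        raise ValueError(f"unknown policy {policy!r}")
    a = plain.set_index("gene_id")
    b = acid.set_index("gene_id")
    genes = a.index.union(b.index)
    rows = []
    for g in genes:
        ra = a.loc[g] if g in a.index else None
        rb = b.loc[g] if g in b.index else None
        cands = [r for r in (ra, rb) if r is not None]
        sig = [r for r in cands if bool(r["significant"])]
        if policy == "either":
            chosen = max(sig, key=lambda r: abs(r["log2fc"])) if sig else max(
                cands, key=lambda r: abs(r["log2fc"])
            )
            significant = bool(sig)
        else:  # both
            significant = len(sig) == 2 and len(cands) == 2
            chosen = max(cands, key=lambda r: abs(r["log2fc"]))
        rows.append(
            {
                "gene_id": g,
                "mean_fpkm_A": float(chosen["mean_fpkm_A"]),
                "mean_fpkm_B": float(chosen["mean_fpkm_B"]),
                "log2fc": float(chosen["log2fc"]),
                "p_value": float(chosen["p_value"]),
                "significant": significant,
            }
        )
    return pd.DataFrame(rows)


def summarize_regulon(entries: list[RegulonEntry], orphans: list[Peak] | None = None) -> dict:
    """Counts over the reconstructed regulon (direct TUs only for genes)."""
    direct = [e for e in entries if e.mode in ("activated_by_TF", "repressed_by_TF")]
    genes_up = genes_down = genes_nonsig = 0
    for e in direct:
        for g in e.gene_ids:
            if g in e.de_genes:
                if e.de_response > 0 and e.mode == "repressed_by_TF":
                    genes_up += 1
                elif e.mode == "activated_by_TF":
                    genes_down += 1
                else:
                    genes_up += 1
            else:
                genes_nonsig += 1
    n_genes = sum(len(e.gene_ids) for e in direct)
    return {
        "n_TUs": len(direct),
        "n_genes": n_genes,
        "n_up": genes_up,
        "n_down": genes_down,
        "n_nonsig": genes_nonsig,
        "n_bound_only": sum(1 for e in entries if e.mode == "bound_only"),
        "n_indirect": sum(1 for e in entries if e.mode == "indirect"),
        "n_orphan_peaks": len(orphans or []),
    }


def entries_to_frame(entries: list[RegulonEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tu_id": e.tu_id,
                "gene_ids": ",".join(e.gene_ids),
                "bound": int(e.bound),
                "de_response": e.de_response,
                "mode": e.mode,
                "peak_ids": ",".join(e.peak_ids),
                "de_genes": ",".join(e.de_genes),
            }
            for e in entries
        ],
        columns=["tu_id", "gene_ids", "bound", "de_response", "mode", "peak_ids", "de_genes"],
    )
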