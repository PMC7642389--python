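"""Five-category candidate prioritization over the regulon/DEG universe.

The cascade narrows the regulon + DEG gene universe to a shortlist of
operons worth functional follow-up. An operon is flagged when it satisfies
any of five categories:

1. ``promoter_divergence`` — its promoter differs between a tolerant and a
   non-responsive strain (supplied as a boolean input table; cross-strain
   sequence comparison is outside this package);
2. ``high_fold_change`` — up-regulated by TF deletion at or above a linear
   fold threshold (default 10);
3. ``acid_resistance_regulator`` — annotated as a general acid-resistance
   regulator;
4. ``membrane_synthesis`` — annotated membrane-synthesis function;
5. ``unknown_function`` — no annotated function.

The shortlist is the union of flagged operons; adding a flag can only grow
it (monotone).
"""

from __future__ import annotations

import logging

import pandas as pd

from .models import CANDIDATE_FLAGS, CandidateRecord, GeneFeature, RegulonEntry

log = logging.getLogger("regulonscope.prioritize")


def flag_candidates(
    regulon_entries: list[RegulonEntry],
    de_results: pd.DataFrame,
    gene_metadata: dict[str, str],
    promoter_comparison: dict[str, bool] | None = None,
    fc_threshold: float = 10.0,
) -> list[CandidateRecord]:
    """Apply the five category rules to every operon in the universe.

    The universe is every TU in ``regulon_entries`` (binding or expression
    evidence; ``none``-mode TUs are carried with no flags so the record set
    is complete). ``gene_metadata`` maps gene -> function class; genes
    without metadata default to unknown function, logged.
    ``high_fold_change`` uses the deletion-vs-wild-type comparison:
    2**log2fc >= fc_threshold for any significant member gene.
    """
    promoter_comparison = promoter_comparison or {}
    de = de_results.set_index("gene_id")
    records: list[CandidateRecord] = []
    for e in regulon_entries:
        flags = {f: False for f in CANDIDATE_FLAGS}
        reasons: list[str] = []
        if promoter_comparison.get(e.tu_id, False):
            flags["promoter_divergence"] = True
            reasons.append("promoter diverges in non-responsive strain")
        for gid in e.gene_ids:
            if gid in de.index and bool(de.loc[gid, "significant"]):
                fold = 2.0 ** float(de.loc[gid, "log2fc"])
                if fold >= fc_threshold:
                    flags["high_fold_change"] = True
                    reasons.append(f"{gid} up {fold:.1f}-fold on TF deletion")
            fclass = gene_metadata.get(gid)
            if fclass is None:
                log.warning("gene %s has no metadata; treated as unknown function", gid)
                fclass = "unknown"
            if fclass == "acid_resistance":
                flags["acid_resistance_regulator"] = True
                reasons.append(f"{gid} is an acid-resistance regulator")
            elif fclass == "membrane_synthesis":
                flags["membrane_synthesis"] = True
                reasons.append(f"{gid} synthesizes membrane components")
            elif fclass == "unknown":
                flags["unknown_function"] = True
                reasons.append(f"{gid} has unknown function")
        in_universe = e.mode != "none"
        records.append(
            CandidateRecord(
                operon_id=e.tu_id,
                gene_ids=list(e.gene_ids),
                flags=flags,
                selected=in_universe and any(flags.values()),
                rationale="; ".join(reasons),
            )
        )
    return records


def select_candidates(records: list[CandidateRecord]) -> dict:
    """Union of flagged operons: the candidate shortlist.

    Ordered by flag count (descending), then input order. Returns operon
    ids, total member-gene count and the records themselves.
    """
    chosen = [r for r in records if r.selected]
    chosen.sort(key=lambda r: (-r.n_flags, records.index(r)))
    return {
        "operons": [r.operon_id for r in chosen],
        "n_operons": len(chosen),
        "genes": [g for r in chosen for g in r.gene_ids],
        "n_genes": sum(len(r.gene_ids) for r in chosen),
        "records": chosen,
    }


# ---------------------------------------------------------------------------
# Worked example: the curated YieP-regulon category table
# ---------------------------------------------------------------------------

#: Literature-curated category membership for the YieP / 3-HP tolerance
#: cascade: category -> operons, with operon gene counts below. The
#: promoter-divergence column is an input (the strain comparison that
#: produced it is outside this package's scope).
EXAMPLE_CATEGORIES: dict[str, tuple[str, ...]] = {
    "promoter_divergence": ("ykgEFG", "sdaCB"),
    "high_fold_change": ("ykgEFG", "yohJK", "adiY"),
    "acid_resistance_regulator": ("gadX", "adiY"),
    "membrane_synthesis": ("rydC",),
    "unknown_function": ("ydcA",),
}

#: Gene membership of each operon in the worked example.
EXAMPLE_OPERON_GENES: dict[str, tuple[str, ...]] = {
    "ykgEFG": ("ykgE", "ykgF", "ykgG"),
    "sdaCB": ("sdaC", "sdaB"),
    "yohJK": ("yohJ", "yohK"),
    "adiY": ("adiY",),
    "gadX": ("gadX",),
    "rydC": ("rydC",),
    "ydcA": ("ydcA",),
}


def example_candidate_records(
    categories: dict[str, tuple[str, ...]] | None = None,
    operon_genes: dict[str, tuple[str, ...]] | None = None,
) -> list[CandidateRecord]:
    """Build CandidateRecords straight from a curated category table.

    Used for the worked example where category membership is already known
    (no DE table or regulon needed): every operon named in any category is
    in the universe and selected.
    """
    categories = categories or EXAMPLE_CATEGORIES
    operon_genes = operon_genes or EXAMPLE_OPERON_GENES
    operons: dict[str, dict[str, bool]] = {}
    for flag, members in categories.items():
        if flag not in CANDIDATE_FLAGS:
            raise ValueError(f"unknown category {flag!r}")
        for op in members:
            operons.setdefault(op, {f: False for f in CANDIDATE_FLAGS})[flag] = True
    records = []
    for op, flags in operons.items():
        if op not in operon_genes:
            raise ValueError(f"operon {op} has no gene list")
        records.append(
            CandidateRecord(
                operon_id=op,
                gene_ids=list(operon_genes[op]),
                flags=flags,
                selected=any(flags.values()),
                rationale="curated category table",
            )
        )
    return records
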