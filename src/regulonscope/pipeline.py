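"""End-to-end orchestration: simulate -> peaks -> DE -> motif -> regulon ->
prioritize, with a reproducibility manifest.

Stages communicate only via on-disk formats so each can be rerun or swapped
independently; rerunning with the same scenario, config and seed reproduces
every output byte-for-byte (the manifest records input/output digests and
the config snapshot; timestamps live only in the manifest itself).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import diffexpr, io_formats, motif as motif_mod, peaks as peaks_mod, prioritize, regulon
from .config import RunConfig
from .diffexpr import ExpressionMatrix
from .synthetic import Scenario, simulate_scenario, write_dataset

log = logging.getLogger("regulonscope.pipeline")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(
    outdir: str | Path,
    scenario: Scenario | None = None,
    config: RunConfig | None = None,
    seed: int = 0,
    de_policy: str = "either",
) -> dict:
    """Run the full pipeline on a simulated scenario; returns the manifest.

    Outputs land in ``outdir``: the simulated dataset, per-replicate and
    merged peak tables, DE tables for both media conditions, the PWM and
    motif report, the regulon table with orphan peaks and summary, and the
    candidate shortlist. A ``manifest.json`` snapshots config, seed and
    output digests.
    """
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config or RunConfig(seed=seed)
    sc = scenario or Scenario()

    log.info("stage=simulate seed=%d", seed)
    ds = simulate_scenario(sc, seed=seed)
    paths = write_dataset(ds, outdir)

    log.info("stage=peaks replicates=%d", len(ds.coverage))
    rep_peaks = []
    for i, cov in enumerate(ds.coverage, start=1):
        called = peaks_mod.call_peaks(
            cov, cfg, border_offset=sc.border_offset, peak_id_prefix=f"rep{i}"
        )
        rep_peaks.append(called)
        io_formats.write_peaks(called, outdir / f"peaks_rep{i}.tsv")
    merged = rep_peaks[0]
    for other in rep_peaks[1:]:
        merged = peaks_mod.merge_replicates(merged, other, max_dist=cfg.merge_max_dist)
    merged = peaks_mod.annotate_peaks(merged, ds.genes)
    io_formats.write_peaks(merged, outdir / "peaks.tsv", outdir / "peaks.bed",
                           seqid=ds.genome.name)
    paths["peaks"] = outdir / "peaks.tsv"
    # downstream stages use peaks reproduced in every replicate (the point of
    # biological duplicates); single-replicate peaks stay flagged in peaks.tsv
    if len(rep_peaks) > 1:
        reproducible = [p for p in merged if p.replicate_support == len(rep_peaks)]
    else:
        reproducible = merged

    log.info("stage=de policy=%s", de_policy)
    lengths = pd.Series({g.gene_id: g.length for g in ds.genes}, name="length")
    mat = ExpressionMatrix(counts=ds.counts, gene_lengths=lengths, samples=ds.samples)
    sm = ds.samples
    def group(strain: str, media: str) -> list[str]:
        return sm[(sm["strain"] == strain) & (sm["media"] == media)]["sample"].tolist()

    de_plain = diffexpr.test_differential(mat, group("WT", "plain"), group("dTF", "plain"), cfg)
    de_acid = diffexpr.test_differential(mat, group("WT", "acid"), group("dTF", "acid"), cfg)
    de_plain.to_csv(outdir / "de_dTF_vs_WT_plain.tsv", sep="\t", index=False)
    de_acid.to_csv(outdir / "de_dTF_vs_WT_acid.tsv", sep="\t", index=False)
    de_combined = regulon.combine_de_tables(de_plain, de_acid, policy=de_policy)
    de_combined.to_csv(outdir / "de_combined.tsv", sep="\t", index=False)
    paths["de_combined"] = outdir / "de_combined.tsv"

    log.info("stage=motif n_peaks=%d", len(reproducible))
    pwm, report = motif_mod.discover_motif(ds.genome, reproducible, cfg, seed=seed)
    pd.DataFrame(pwm.probs, index=list("ACGT")).to_csv(outdir / "pwm.tsv", sep="\t")
    with open(outdir / "motif_report.json", "w") as fh:
        json.dump(
            {
                "consensus": report.consensus,
                "ic_bits": [round(float(x), 4) for x in report.ic],
                "palindrome_distance": round(report.palindrome_distance, 4),
                "n_sites": pwm.n_sites,
            },
            fh,
            indent=2,
        )
    paths["motif_report"] = outdir / "motif_report.json"

    log.info("stage=regulon promoter_window=%d", cfg.promoter_window)
    assignments, orphans = regulon.map_peaks_to_tus(
        reproducible, ds.tus, cfg.promoter_window, ds.genome.length
    )
    entries = regulon.classify_regulation(assignments, de_combined, ds.tus, cfg)
    regulon.entries_to_frame(entries).to_csv(outdir / "regulon.tsv", sep="\t", index=False)
    io_formats.write_peaks(orphans, outdir / "orphan_peaks.tsv")
    summary = regulon.summarize_regulon(entries, orphans)
    with open(outdir / "regulon_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    paths["regulon"] = outdir / "regulon.tsv"

    log.info("stage=prioritize")
    meta = {g.gene_id: g.function_class for g in ds.genes}
    records = prioritize.flag_candidates(entries, de_combined, meta)
    shortlist = prioritize.select_candidates(records)
    pd.DataFrame(
        [
            {
                "operon_id": r.operon_id,
                "gene_ids": ",".join(r.gene_ids),
                **{f: int(v) for f, v in r.flags.items()},
                "selected": int(r.selected),
                "rationale": r.rationale,
            }
            for r in shortlist["records"]
        ]
    ).to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    paths["candidates"] = outdir / "candidates.tsv"

    manifest = {
        "seed": seed,
        "config": cfg.to_dict(),
        "scenario": dataclasses.asdict(sc),
        "de_policy": de_policy,
        "outputs": {k: {"path": str(v), "sha256": _sha256(Path(v))} for k, v in paths.items()},
        "n_peaks": len(merged),
        "regulon_summary": summary,
        "n_candidate_operons": shortlist["n_operons"],
        "elapsed_s": round(time.time() - t0, 2),
        "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    log.info("stage=done elapsed=%.1fs", manifest["elapsed_s"])
    return manifest
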