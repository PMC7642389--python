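"""Exact utilities for the phenotype readouts.

* ΔΔCt relative expression from qPCR cycle-threshold tables (fold =
  2^-ΔΔCt, replicates averaged on the Ct scale, reference gene per
  strain/condition — standard relative quantification, no efficiency
  correction);
* specific fluorescence = GFP / OD600 for biosensor tables;
* MIC from growth-vs-concentration tables: the lowest tested concentration
  at which growth stops (OD below threshold) and stays stopped at every
  higher tested concentration (monotone envelope rule).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .models import MICResult

log = logging.getLogger("regulonscope.assays")

CT_COLUMNS = ["strain", "condition", "gene", "replicate", "ct"]
GROWTH_COLUMNS = ["strain", "acid", "concentration", "od600"]
FLUOR_COLUMNS = ["strain", "hp_mM", "gfp", "od600"]


def _mean_ct(table: pd.DataFrame, strain: str, condition: str, gene: str) -> float:
    rows = table[
        (table["strain"] == strain)
        & (table["condition"] == condition)
        & (table["gene"] == gene)
    ]
    if rows.empty:
        raise ValueError(f"no Ct rows for {gene} in ({strain}, {condition})")
    if (rows["ct"] <= 0).any():
        raise ValueError("Ct values must be > 0")
    return float(rows["ct"].mean())


def ddct(
    table: pd.DataFrame,
    target: str,
    reference: str,
    baseline: tuple[str, str],
    test: tuple[str, str],
) -> float:
    """Relative expression of ``target`` in ``test`` vs ``baseline``.

    ΔCt = Ct_target - Ct_reference within each (strain, condition);
    ΔΔCt = ΔCt_test - ΔCt_baseline; fold = 2^-ΔΔCt. Replicates are
    averaged on the Ct (log) scale before differencing.
    """
    d_base = _mean_ct(table, *baseline, target) - _mean_ct(table, *baseline, reference)
    d_test = _mean_ct(table, *test, target) - _mean_ct(table, *test, reference)
    return float(2.0 ** -(d_test - d_base))


def ddct_table(
    table: pd.DataFrame,
    targets: list[str],
    reference: str,
    baseline: tuple[str, str],
) -> pd.DataFrame:
    """Fold change of every target in every (strain, condition) vs baseline."""
    conditions = (
        table[["strain", "condition"]].drop_duplicates().itertuples(index=False)
    )
    rows = []
    for strain, condition in conditions:
        for target in targets:
            rows.append(
                {
                    "strain": strain,
                    "condition": condition,
                    "gene": target,
                    "fold_change": ddct(
                        table, target, reference, baseline, (strain, condition)
                    ),
                }
            )
    return pd.DataFrame(rows)


def normalize_fluorescence(table: pd.DataFrame) -> pd.DataFrame:
    """Specific fluorescence (AU/OD600) per row; OD600 == 0 rows excluded.

    Homogeneous of degree 1 in GFP and -1 in OD by construction.
    """
    out = table.copy()
    bad = out["od600"] <= 0
    if bad.any():
        log.warning("excluding %d rows with OD600 <= 0", int(bad.sum()))
        out = out[~bad].copy()
    out["specific_fluorescence"] = out["gfp"] / out["od600"]
    return out


def determine_mic(
    table: pd.DataFrame,
    od_threshold: float = 0.1,
    strain: str | None = None,
    acid: str | None = None,
) -> MICResult:
    """MIC from an OD-vs-concentration profile (monotone envelope rule).

    The MIC is the lowest tested concentration whose OD is below
    ``od_threshold`` with every *higher* tested concentration also below
    threshold. Growth at the highest tested concentration returns an
    above-range sentinel. A non-monotone profile (growth resuming above a
    no-growth concentration) still yields the envelope MIC, with the
    violating concentrations listed as warnings.
    """
    sub = table
    if strain is not None:
        sub = sub[sub["strain"] == strain]
    if acid is not None:
        sub = sub[sub["acid"] == acid]
    if sub.empty:
        raise ValueError("no growth rows for the requested profile")
    prof = (
        sub.groupby("concentration")["od600"].mean().sort_index()
    )
    if len(prof) < 2:
        raise ValueError("need at least 2 tested concentrations")
    if (prof.index < 0).any():
        raise ValueError("negative concentration")

    conc = prof.index.to_numpy(dtype=float)
    growth = prof.to_numpy(dtype=float) >= od_threshold

    warnings: list[str] = []
    if growth[-1]:
        # growth at the top of the tested range; flag any interior dips
        for c, g in zip(conc[:-1], growth[:-1]):
            if not g:
                warnings.append(f"no growth at {c:g} mM but growth at higher concentration")
        return MICResult(mic_mM=None, above_range=True, warnings=warnings)

    # walk down from the top: MIC = start of the terminal no-growth run
    i = len(conc) - 1
    while i > 0 and not growth[i - 1]:
        i -= 1
    for c, g in zip(conc[:i], growth[:i]):
        if not g:
            warnings.append(f"non-monotone profile: no growth at {c:g} mM below the MIC")
    return MICResult(mic_mM=float(conc[i]), above_range=False, warnings=warnings)


def growth_significance(
    table: pd.DataFrame, strain_a: str, strain_b: str, acid: str, concentration: float
) -> float:
    """Welch's t-test p-value comparing OD600 of two strains at one dose.

    A convenience for per-acid strain comparisons; two-sided.
    """
    from scipy import stats

    sel = (table["acid"] == acid) & (table["concentration"] == concentration)
    a = table[sel & (table["strain"] == strain_a)]["od600"]
    b = table[sel & (table["strain"] == strain_b)]["od600"]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per strain")
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
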