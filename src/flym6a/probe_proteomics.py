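"""Scoring of m6A-probe vs A-probe pulldown spectral counts.

Proteins must be recovered in both replicate datasets to be scored; all
counts get a pseudocount of 1 so single-probe identifications have defined
log2(m6A/A) enrichment ratios; and proteins are classified as bound
(reader), repelled, or background by quartile fences at 2x the
interquartile range, required in both replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("protein", "probe", "replicate", "count")


@dataclass
class ClassifierParams:
    pseudocount: float = 1.0
    iqr_mult: float = 2.0
    mode: str = "per_replicate"  # or "pooled": fences from pooled ratios

    def __post_init__(self):
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.iqr_mult <= 0:
            raise ValueError("iqr_mult must be positive")
        if self.mode not in ("per_replicate", "pooled"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    if table.empty:
        raise ValueError("empty spectral-count table")
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"table lacks columns: {sorted(missing)}")
    if (table["count"] < 0).any():
        raise ValueError("negative spectral counts")
    dup = table.duplicated(["protein", "probe", "replicate"])
    if dup.any():
        raise ValueError("duplicate (protein, probe, replicate) rows")
    if "present" not in table.columns:
        table = table.assign(present=True)
    return table


def filter_consistent(table: pd.DataFrame) -> Tuple[pd.DataFrame, int]:
    """Retain proteins recovered in both replicates; report how many were
    removed.

    A protein counts as recovered in a replicate when any of its rows for
    that replicate is flagged present (rows simply absent from the table
    also count as not recovered).
    """
    table = _check_table(table)
    recovered = (
        table[table["present"]]
        .groupby("protein")["replicate"]
        .nunique()
    )
    replicates = table["replicate"].nunique()
    keep = set(recovered.index[recovered == replicates])
    n_total = table["protein"].nunique()
    retained = table[table["protein"].isin(keep)].reset_index(drop=True)
    return retained, n_total - len(keep)


def enrichment_ratios(
    table: pd.DataFrame, params: ClassifierParams | None = None
) -> pd.DataFrame:
    """Per-replicate log2((count_m6A + pc) / (count_A + pc)), one row per
    protein, columns rep1, rep2, ... in replicate order."""
    params = params or ClassifierParams()
    table = _check_table(table)
    pc = params.pseudocount
    wide = table.pivot_table(
        index="protein",
        columns=["replicate", "probe"],
        values="count",
        fill_value=0,
        aggfunc="sum",
    )
    out = {}
    for rep in sorted(table["replicate"].unique()):
        m6a = wide.get((rep, "m6A"), pd.Series(0, index=wide.index))
        a = wide.get((rep, "A"), pd.Series(0, index=wide.index))
        out[f"rep{rep}"] = np.log2((m6a + pc) / (a + pc))
    return pd.DataFrame(out).sort_index()


def classify_binders(
    ratios: pd.DataFrame, params: ClassifierParams | None = None
) -> pd.DataFrame:
    """Bound / repelled / background by 2x-IQR quartile fences.

    A protein is *bound* when its log2 ratio lies strictly above
    Q3 + iqr_mult x IQR in every replicate, *repelled* when strictly below
    Q1 - iqr_mult x IQR in every replicate, else *background*.  In
    "pooled" mode the fences come from all replicates' ratios combined but
    membership is still required in each replicate.
    """
    params = params or ClassifierParams()
    if len(ratios) < 4:
        raise ValueError("need at least 4 proteins for stable quartiles")
    rep_cols = list(ratios.columns)
    fences = {}
    if params.mode == "pooled":
        pooled = ratios.to_numpy().ravel()
        q1, q3 = np.percentile(pooled, [25, 75])
        iqr = q3 - q1
        for col in rep_cols:
            fences[col] = (q1 - params.iqr_mult * iqr, q3 + params.iqr_mult * iqr)
    else:
        for col in rep_cols:
            q1, q3 = np.percentile(ratios[col], [25, 75])
            iqr = q3 - q1
            fences[col] = (q1 - params.iqr_mult * iqr, q3 + params.iqr_mult * iqr)
    above = np.all(
        [ratios[c] > fences[c][1] for c in rep_cols], axis=0
    )
    below = np.all(
        [ratios[c] < fences[c][0] for c in rep_cols], axis=0
    )
    out = ratios.copy()
    out["class"] = np.where(above, "bound", np.where(below, "repelled", "background"))
    return out


def score_binders(
    table: pd.DataFrame, params: ClassifierParams | None = None
) -> Tuple[pd.DataFrame, int]:
    """Full scoring chain: consistency filter -> pseudocounted ratios ->
    2x-IQR classification.  Returns (classification, n_removed)."""
    params = params or ClassifierParams()
    retained, n_removed = filter_consistent(table)
    ratios = enrichment_ratios(retained, params)
    return classify_binders(ratios, params), n_removed
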