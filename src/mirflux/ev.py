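"""EV vs whole-worm miRNAome comparison: loading ratios and secretion classes.

The relative abundance of a miRNA in a compartment (whole worm or EV) at one
age is its replicate-mean UMI count divided by the summed replicate-mean UMIs
of all miRNAs detected in that compartment-age, so fractions sum to 1 over
the detected set.  The EV loading ratio is the miRNA's relative abundance in
EVs over that in the whole worm; its D8/D1 ratio classifies age-dependent
selective secretion: promoted when the change exceeds the fold threshold
(strict > 2 by default), suppressed when below its reciprocal, stable in
between, and undetermined when the miRNA is missing on one side.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .datatypes import DetectionTable, ExpressionMatrix

logger = logging.getLogger("mirflux")

SECRETION_CLASSES = ("promoted", "suppressed", "stable", "undetermined")


def relative_abundance(
    em: ExpressionMatrix, detection: DetectionTable, pooled: bool = False
) -> pd.DataFrame:
    """Per compartment-age miRNA fractions over the detected set.

    Returns a mature x (compartment, age) table; undetected miRNAs hold NaN
    and are excluded from the denominator.  ``pooled=True`` sums UMIs across
    replicates instead of averaging (identical fractions when all replicates
    are present; offered for pooled-library workflows).
    """
    if em.scale != "raw_count":
        raise ValueError("relative abundance is computed from raw UMI counts")
    out = pd.DataFrame(
        np.nan, index=em.values.index, columns=detection.per_group.columns
    )
    for key in detection.per_group.columns:
        cols = em.group_columns(*key)
        if not cols:
            continue
        detected = detection.per_group[key]
        if not detected.any():
            raise ValueError(f"no miRNA detected in compartment-age {key}")
        agg = em.values[cols].sum(axis=1) if pooled else em.values[cols].mean(axis=1)
        denom = float(agg[detected].sum())
        out.loc[detected, key] = agg[detected] / denom
    return out


def loading_ratio(
    rel: pd.DataFrame,
    cfg: AnalysisConfig | None = None,
    ev_label: str = "EV",
    worm_label: str = "Worm",
) -> pd.DataFrame:
    """EV loading ratio table per miRNA and age, with the age change.

    Columns: rel_worm_d1, rel_ev_d1, ratio_d1, rel_worm_d8, rel_ev_d8,
    ratio_d8, age_change, secretion_class, reason.  Ratios require joint
    detection in both compartments at that age; otherwise NaN.  The class is
    assigned by :func:`classify_secretion` semantics and is ``undetermined``
    (with a reason code) when either age's ratio is unavailable.
    """
    cfg = cfg or AnalysisConfig()
    d1, d8 = cfg.ages
    ages = {d1: "d1", d8: "d8"}
    table = pd.DataFrame(index=rel.index)
    for age, tag in ages.items():
        worm = rel[(worm_label, age)]
        ev = rel[(ev_label, age)]
        if (worm == 0).any():  # NaN compares False: only detected rows can trip this
            raise ValueError(
                f"zero whole-worm abundance with detection at {age}: "
                f"{list(rel.index[worm == 0])}"
            )
        table[f"rel_worm_{tag}"] = worm
        table[f"rel_ev_{tag}"] = ev
        table[f"ratio_{tag}"] = ev / worm
    table["age_change"] = table["ratio_d8"] / table["ratio_d1"]
    table = classify_secretion(table, cfg.loading_fold_threshold)
    return table


def classify_secretion(table: pd.DataFrame, fold_threshold: float = 2.0) -> pd.DataFrame:
    """Assign secretion classes from the age change of the loading ratio.

    Strict inequalities: promoted iff age_change > fold_threshold,
    suppressed iff age_change < 1/fold_threshold (an age change of exactly
    the threshold is stable).  Rows lacking either age's ratio are
    undetermined with a reason code.
    """
    if fold_threshold <= 0:
        raise ValueError("fold_threshold must be positive")
    out = table.copy()
    change = out["age_change"]
    cls = np.where(
        change.isna(),
        "undetermined",
        np.where(
            change > fold_threshold,
            "promoted",
            np.where(change < 1.0 / fold_threshold, "suppressed", "stable"),
        ),
    )
    out["secretion_class"] = cls
    reason = np.where(
        out["ratio_d1"].isna() & out["ratio_d8"].isna(),
        "not_jointly_detected",
        np.where(
            out["ratio_d1"].isna(),
            "missing_d1",
            np.where(out["ratio_d8"].isna(), "missing_d8", ""),
        ),
    )
    out["reason"] = reason
    counts = out["secretion_class"].value_counts()
    logger.info("secretion classes: %s", counts.to_dict())
    return out


def secretion_class_sets(table: pd.DataFrame) -> dict[str, set[str]]:
    """Per-class miRNA id sets from a classified loading-ratio table."""
    return {
        cls: set(table.index[table["secretion_class"] == cls])
        for cls in SECRETION_CLASSES
    }
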