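"""Normalisation, detection calling and ordination QC.

Mature miRNAs are treated as equal effective length, so TPM reduces to a
per-million share of the column: counts * 1e6 / column sum.  Quantile
normalisation is applied to log2(TPM + pseudocount); detection is called
per replicate and per (tissue, age) group with the read rule (strict > 5)
or, for UMI libraries, the group-sum rule (>= 10 UMIs over the replicates).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .config import GROUP_RULES, AnalysisConfig
from .datatypes import DetectionTable, ExpressionMatrix

logger = logging.getLogger("mirflux")


def compute_tpm(em: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each raw-count column to transcripts-per-million.

    With equal-length features TPM is the per-column proportion times 1e6,
    so every column of the result sums to one million.
    """
    if em.scale != "raw_count":
        raise ValueError(f"compute_tpm expects raw counts, got scale={em.scale!r}")
    colsums = em.values.sum(axis=0)
    zero = colsums[colsums <= 0]
    if len(zero):
        raise ValueError(f"all-zero count column(s): {list(zero.index)}")
    tpm = em.values / colsums * 1e6
    return em.with_values(tpm, "tpm")


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalise columns to the mean-of-sorted-columns reference.

    Tied values within a column receive the mean of the reference quantiles
    they span (via average ranks with linear interpolation), which keeps the
    transform deterministic and order-independent.
    """
    ref = np.sort(df.to_numpy(), axis=0).mean(axis=1)
    n = len(ref)
    ranks = df.rank(method="average").to_numpy()  # in [1, n], possibly half-integer
    # interpolate the reference at (rank - 1); ties at .5 ranks average neighbours
    out = np.interp(ranks - 1.0, np.arange(n), ref)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def log2_and_quantile_normalize(
    em: ExpressionMatrix, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """log2(TPM + pseudocount) followed by quantile normalisation."""
    if em.scale != "tpm":
        raise ValueError(f"expected a tpm matrix, got scale={em.scale!r}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logged = np.log2(em.values + pseudocount)
    qn = quantile_normalize(logged)
    return em.with_values(qn, "qnorm_log2tpm")


def _group_map(em: ExpressionMatrix) -> dict[tuple[str, str], list[str]]:
    groups: dict[tuple[str, str], list[str]] = {}
    for key in em.groups():
        cols = em.group_columns(*key)
        if not cols:
            logger.warning("empty sample group %s skipped", key)
            continue
        groups[key] = cols
    return groups


def call_detection_reads(
    em: ExpressionMatrix, threshold: float = 5.0, group_rule: str = "mean"
) -> DetectionTable:
    """Detection calls for read-count libraries.

    Per replicate: count strictly greater than ``threshold``.  Per (tissue,
    age) group: under the default ``mean`` rule, mean replicate count > threshold;
    ``any``/``all`` instead combine the replicate calls.
    """
    if em.scale != "raw_count":
        raise ValueError("detection is called on raw counts")
    if group_rule not in GROUP_RULES:
        raise ValueError(f"group_rule must be one of {GROUP_RULES}")
    per_rep = em.values > threshold
    groups = _group_map(em)
    cols = pd.MultiIndex.from_tuples(list(groups), names=["tissue", "age"])
    per_group = pd.DataFrame(False, index=em.values.index, columns=cols)
    for key, samples in groups.items():
        block = em.values[samples]
        if group_rule == "mean":
            call = block.mean(axis=1) > threshold
        elif group_rule == "any":
            call = (block > threshold).any(axis=1)
        else:
            call = (block > threshold).all(axis=1)
        per_group[key] = call
    logger.info(
        "detection (reads, rule=%s, >%g): %d/%d miRNAs expressed in >=1 group",
        group_rule,
        threshold,
        int(per_group.any(axis=1).sum()),
        em.n_features,
    )
    return DetectionTable(per_replicate=per_rep, per_group=per_group)


def call_detection_umi(em: ExpressionMatrix, threshold: float = 10.0) -> DetectionTable:
    """Detection calls for UMI libraries: group UMI sum >= threshold.

    The replicate-level table uses a per-replicate share of the group
    threshold only for bookkeeping (count > 0); group calls are the contract.
    """
    if em.scale != "raw_count":
        raise ValueError("detection is called on raw UMI counts")
    if not (em.samples["count_unit"] == "UMI").all():
        raise ValueError("call_detection_umi expects UMI libraries")
    per_rep = em.values > 0
    groups = _group_map(em)
    for key, samples in groups.items():
        if len(samples) != 3:
            logger.warning(
                "group %s has %d replicates (expected 3); UMI-sum rule applied anyway",
                key,
                len(samples),
            )
    cols = pd.MultiIndex.from_tuples(list(groups), names=["tissue", "age"])
    per_group = pd.DataFrame(False, index=em.values.index, columns=cols)
    for key, samples in groups.items():
        per_group[key] = em.values[samples].sum(axis=1) >= threshold
    logger.info(
        "detection (UMI sum >= %g): %d/%d miRNAs expressed in >=1 group",
        threshold,
        int(per_group.any(axis=1).sum()),
        em.n_features,
    )
    return DetectionTable(per_replicate=per_rep, per_group=per_group)


def ordination_qc(em: ExpressionMatrix) -> dict:
    """Sample-level QC: PCA, sample-sample Pearson matrix and a dendrogram.

    PCA is run on feature-centred values with samples as observations.
    Clustering uses average linkage on correlation distance (1 - r);
    constant samples (undefined correlation) are flagged and excluded.
    """
    if em.n_samples < 2:
        raise ValueError("ordination needs at least 2 samples")
    X = em.values.to_numpy(dtype=float)
    sample_ids = list(em.values.columns)

    centred = X - X.mean(axis=1, keepdims=True)
    n_comp = min(len(sample_ids), X.shape[0], 10)
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(centred.T)
    pca_df = pd.DataFrame(
        coords, index=sample_ids, columns=[f"PC{i + 1}" for i in range(n_comp)]
    )

    sds = X.std(axis=0)
    constant = [s for s, sd in zip(sample_ids, sds) if sd == 0]
    if constant:
        logger.warning("constant sample vectors excluded from clustering: %s", constant)
    keep = [s for s in sample_ids if s not in constant]
    corr = pd.DataFrame(
        np.corrcoef(X.T), index=sample_ids, columns=sample_ids
    )
    link = None
    if len(keep) >= 2:
        sub = corr.loc[keep, keep].to_numpy()
        dist = 1.0 - sub
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        link = linkage(squareform(dist, checks=False), method="average")
    return {
        "pca_coordinates": pca_df,
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "pearson_matrix": corr,
        "dendrogram_linkage": link,
        "clustered_samples": keep,
    }
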