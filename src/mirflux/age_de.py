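"""Age-dependent differential expression of miRNAs (D1 vs D8).

Per tissue, each miRNA expressed there at either age is tested with a
two-sided pooled-variance Student t-test on Box-Cox-transformed TPM (the
power transform is fitted by maximum likelihood on the pooled D1+D8 values
of that miRNA in that tissue, so both groups share one monotone transform).
No multiple-testing adjustment is applied to the significance call; a
Benjamini-Hochberg FDR column is emitted for reference.

Two criteria are supported:

* ``tissue`` mode: significant iff p < p_threshold (the per-tissue call);
* ``compartment`` mode (whole-worm / EV libraries): additionally requires
  fold change > fc_threshold or < 1/fc_threshold.

miRNAs significant in at least one tissue form the Age-DEMIR set
(age-dependent differentially expressed miRNAs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .datatypes import DetectionTable, ExpressionMatrix

logger = logging.getLogger("mirflux")

DE_COLUMNS = [
    "mature_id",
    "tissue",
    "mean_d1",
    "mean_d8",
    "fold_change",
    "lambda",
    "t",
    "p",
    "fdr",
    "significant",
    "direction",
]


_LAM_GRID = np.linspace(-5.0, 5.0, 201)


def _batch_boxcox_lambda(X: np.ndarray) -> np.ndarray:
    """Maximum-likelihood Box-Cox lambda per row of a positive matrix.

    The profile log-likelihood (lam - 1) * sum(log x) - n/2 * log(var(y))
    is evaluated on a lambda grid and the maximum refined by parabolic
    interpolation; constant rows (any lambda admissible) get lam = 1.
    """
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    L = np.log(X)
    sumL = L.sum(axis=1)
    llf = np.empty((len(_LAM_GRID), m))
    for i, lam in enumerate(_LAM_GRID):
        # var((x^lam - 1)/lam) = var(x^lam)/lam^2, computed on exp(lam*log x)
        # directly to avoid catastrophic cancellation against the constant
        if lam == 0.0:
            logvar = np.log(L.var(axis=1))
        else:
            var = np.exp(lam * L).var(axis=1)
            with np.errstate(divide="ignore"):
                logvar = np.log(var) - 2.0 * np.log(abs(lam))
        llf[i] = np.where(
            np.isfinite(logvar), (lam - 1.0) * sumL - 0.5 * n * logvar, -np.inf
        )
    best = llf.argmax(axis=0)
    lam = _LAM_GRID[best]
    # parabolic refinement where the maximum is interior
    interior = (best > 0) & (best < len(_LAM_GRID) - 1)
    i = best[interior]
    cols = np.nonzero(interior)[0]
    f0, f1, f2 = llf[i - 1, cols], llf[i, cols], llf[i + 1, cols]
    denom = f0 - 2.0 * f1 + f2
    h = _LAM_GRID[1] - _LAM_GRID[0]
    shift = np.where(denom < 0, 0.5 * h * (f0 - f2) / np.where(denom == 0, 1, denom), 0.0)
    lam = lam.copy()
    lam[interior] += np.clip(shift, -h, h)
    lam[X.std(axis=1) == 0] = 1.0  # constant rows: documented tie-break
    return lam


def boxcox_transform(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Box-Cox transform with maximum-likelihood lambda.

    y = (x^lam - 1)/lam for lam != 0, log(x) for lam == 0.  All inputs must
    be strictly positive.  For a constant vector any lambda is admissible;
    the documented tie-break is lam = 1 (y = x - 1).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input to boxcox_transform")
    if (x <= 0).any():
        raise ValueError("Box-Cox requires strictly positive values")
    lam = float(_batch_boxcox_lambda(x[None, :])[0])
    return apply_boxcox(x, lam), lam


def apply_boxcox(x: np.ndarray, lam: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if lam == 0.0:
        return np.log(x)
    return (np.power(x, lam) - 1.0) / lam


def ttest_age(d1: np.ndarray, d8: np.ndarray) -> tuple[float, float]:
    """Two-sided pooled-variance two-sample t-test; returns (t, p).

    The statistic is oriented as D8 minus D1.  Degenerate variance is
    resolved as: equal means -> (t=0, p=1); unequal means with zero pooled
    variance -> (t=+/-inf, p=0) with a log flag.
    """
    a = np.asarray(d1, dtype=float)
    b = np.asarray(d8, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each age group needs at least 2 values")
    pooled_var = (
        ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
        / (len(a) + len(b) - 2)
    )
    if pooled_var == 0.0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        logger.warning("zero pooled variance with unequal means; p -> 0")
        return float(np.sign(b.mean() - a.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(b, a, equal_var=True)
    return float(t), float(p)


def umi_two_proportion_test(k1: float, n1: float, k2: float, n2: float) -> tuple[float, float]:
    """Two-proportion z-test on pooled UMI counts (count-model alternative
    to the transformed t-test for compartment libraries).

    k1/n1 and k2/n2 are the miRNA's pooled UMIs and library totals at the
    two ages; z = (p1 - p2) / sqrt(p*(1-p*)*(1/n1 + 1/n2)) with the pooled
    proportion p*.  Returns (z, two-sided p).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    if se == 0.0:
        return 0.0, 1.0
    z = (p2 - p1) / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class AgeDemirSet:
    """Per-tissue up/down Age-DEMIR sets and their union."""

    per_tissue: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    @property
    def union(self) -> set[str]:
        out: set[str] = set()
        for sets in self.per_tissue.values():
            out |= sets["up"] | sets["down"]
        return out

    def tissue_set(self, tissue: str) -> set[str]:
        sets = self.per_tissue.get(tissue, {"up": set(), "down": set()})
        return sets["up"] | sets["down"]


def call_age_demirs(
    em: ExpressionMatrix,
    detection: DetectionTable,
    cfg: AnalysisConfig | None = None,
    mode: str = "tissue",
) -> tuple[AgeDemirSet, pd.DataFrame]:
    """Test every detected miRNA per tissue for a D1-vs-D8 change.

    ``em`` must be a TPM matrix (compartment mode accepts relative
    abundance); a miRNA is tested in a tissue only if it is expressed there
    at D1 or D8 by the group-level detection call.  Fold change is D8 mean
    over D1 mean on the untransformed scale, after adding the pseudocount.
    """
    cfg = cfg or AnalysisConfig()
    if mode not in ("tissue", "compartment"):
        raise ValueError("mode must be 'tissue' or 'compartment'")
    if em.scale not in ("tpm", "relative_abundance"):
        raise ValueError(f"DE expects tpm or relative_abundance, got {em.scale!r}")

    tissues = [t for t in dict.fromkeys(em.samples["tissue"])]
    records: list[dict] = []
    for tissue in tissues:
        d1_cols = em.group_columns(tissue, cfg.ages[0])
        d8_cols = em.group_columns(tissue, cfg.ages[1])
        if len(d1_cols) < 2 or len(d8_cols) < 2:
            logger.warning("tissue %s lacks a full D1/D8 design; skipped", tissue)
            continue
        has_group = [
            key for key in [(tissue, cfg.ages[0]), (tissue, cfg.ages[1])]
            if key in detection.per_group.columns
        ]
        if not has_group:
            logger.warning("no detection calls for tissue %s; skipped", tissue)
            continue
        tested = detection.per_group[has_group].any(axis=1)
        tested = tested.reindex(em.values.index, fill_value=False).to_numpy()
        keep = np.nonzero(tested)[0]
        if len(keep) == 0:
            continue
        X1 = em.values[d1_cols].to_numpy(dtype=float)[keep]
        X8 = em.values[d8_cols].to_numpy(dtype=float)[keep]
        feature_ids = np.asarray(em.values.index)[keep]
        n1, n8 = X1.shape[1], X8.shape[1]

        pooled = np.hstack([X1, X8]) + cfg.pseudocount
        lams = _batch_boxcox_lambda(pooled)
        Y = np.where(
            lams[:, None] == 0.0,
            np.log(pooled),
            (np.exp(lams[:, None] * np.log(pooled)) - 1.0)
            / np.where(lams[:, None] == 0.0, 1.0, lams[:, None]),
        )
        Y1, Y8 = Y[:, :n1], Y[:, n1:]
        m1, m8 = Y1.mean(axis=1), Y8.mean(axis=1)
        pooled_var = (
            (n1 - 1) * Y1.var(axis=1, ddof=1) + (n8 - 1) * Y8.var(axis=1, ddof=1)
        ) / (n1 + n8 - 2)
        df_t = n1 + n8 - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = (m8 - m1) / np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n8))
            pvals = 2.0 * stats.t.sf(np.abs(tvals), df_t)
        degenerate = pooled_var == 0.0
        if degenerate.any():
            same = degenerate & np.isclose(m1, m8)
            diff = degenerate & ~same
            tvals[same], pvals[same] = 0.0, 1.0
            if diff.any():
                logger.warning(
                    "%d tests with zero pooled variance and unequal means; p -> 0",
                    int(diff.sum()),
                )
                tvals[diff] = np.sign(m8[diff] - m1[diff]) * np.inf
                pvals[diff] = 0.0

        mean_d1, mean_d8 = X1.mean(axis=1), X8.mean(axis=1)
        fc = (mean_d8 + cfg.pseudocount) / (mean_d1 + cfg.pseudocount)
        for j, mature_id in enumerate(feature_ids):
            records.append(
                {
                    "mature_id": mature_id,
                    "tissue": tissue,
                    "mean_d1": float(mean_d1[j]),
                    "mean_d8": float(mean_d8[j]),
                    "fold_change": float(fc[j]),
                    "lambda": float(lams[j]),
                    "t": float(tvals[j]),
                    "p": float(pvals[j]),
                }
            )

    de = pd.DataFrame(records, columns=[c for c in DE_COLUMNS if c not in ("fdr", "significant", "direction")])
    if de.empty:
        de = de.assign(fdr=[], significant=[], direction=[])
        return AgeDemirSet(), de[DE_COLUMNS]

    de["fdr"] = multipletests(de["p"], method="fdr_bh")[1]
    sig = de["p"] < cfg.p_threshold
    if mode == "compartment":
        sig &= (de["fold_change"] > cfg.fc_threshold) | (
            de["fold_change"] < 1.0 / cfg.fc_threshold
        )
    de["significant"] = sig
    de["direction"] = np.where(
        ~sig, "unchanged", np.where(de["fold_change"] > 1.0, "up", "down")
    )

    demirs = AgeDemirSet()
    for tissue, sub in de.groupby("tissue", sort=False):
        demirs.per_tissue[tissue] = {
            "up": set(sub.loc[sub["direction"] == "up", "mature_id"]),
            "down": set(sub.loc[sub["direction"] == "down", "mature_id"]),
        }
    logger.info(
        "DE (%s mode): %d tests, %d significant, %d Age-DEMIRs in union",
        mode,
        len(de),
        int(sig.sum()),
        len(demirs.union),
    )
    return demirs, de[DE_COLUMNS]
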