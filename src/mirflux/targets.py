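"""miRNA target inference and autonomous / non-autonomous partitioning.

A gene is called a target of a miRNA when (i) its 3'UTR carries at least one
canonical seed-match site (8mer, 7mer-m8 or 7mer-A1) and (ii) the Pearson
correlation between the miRNA's and the gene's expression profiles across
the tissue-by-age condition means is below the anti-correlation threshold
(default r < -0.2).  Target calls are then placed into the (tissue, age)
combinations where both partners are expressed; a call is non-autonomous
when the miRNA is PITT (expressed without transcription) in that tissue-age,
autonomous otherwise.

Seed-site nomenclature follows the canonical-site convention: the UTR site
read 5'->3' is the reverse complement of miRNA positions 2-8 (7mer-m8),
positions 2-7 followed by an A opposite position 1 (7mer-A1), or both
(8mer).  Overlapping matches at one seed locus collapse to the strongest
type: 8mer > 7mer-m8 > 7mer-A1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .datatypes import RNA_ALPHABET, check_rna

logger = logging.getLogger("mirflux")

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeedSite:
    """One canonical seed-match site; positions are 1-based inclusive."""

    gene_id: str
    mature_id: str
    site_type: str
    utr_start: int
    utr_end: int

    def __post_init__(self) -> None:
        length = self.utr_end - self.utr_start + 1
        if length not in (7, 8):
            raise ValueError(f"canonical sites are 7 or 8 nt, got {length}")
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")


def find_seed_sites(
    utr: str, mirna: str, gene_id: str = "", mature_id: str = ""
) -> list[SeedSite]:
    """All canonical seed-match sites of one miRNA in one UTR.

    Scans for the seed core (reverse complement of miRNA positions 2-7) and
    classifies each locus by whether the UTR extends the match opposite
    position 8 (m8) and/or presents an A opposite position 1 (A1); loci with
    a bare 6mer core and neither extension are not reported.
    """
    check_rna(utr, name="UTR")
    check_rna(mirna, name="miRNA", min_len=8)
    core = reverse_complement(mirna[1:7])  # pairs miRNA positions 2-7
    m8 = reverse_complement(mirna[7])      # UTR base 5' of the core
    sites: list[SeedSite] = []
    i = utr.find(core)
    while i != -1:
        has_m8 = i >= 1 and utr[i - 1] == m8
        has_a1 = i + 6 < len(utr) and utr[i + 6] == "A"
        if has_m8 and has_a1:
            sites.append(SeedSite(gene_id, mature_id, "8mer", i, i + 7))
        elif has_m8:
            sites.append(SeedSite(gene_id, mature_id, "7mer-m8", i, i + 6))
        elif has_a1:
            sites.append(SeedSite(gene_id, mature_id, "7mer-A1", i + 1, i + 7))
        i = utr.find(core, i + 1)
    return sites


def build_site_table(utrs: dict[str, str], mirnas: dict[str, str]) -> pd.DataFrame:
    """Scan every miRNA against every UTR; tidy site table.

    Columns: mature_id, gene_id, site_type, utr_start, utr_end.
    """
    rows = []
    for mature_id, mseq in mirnas.items():
        for gene_id, useq in utrs.items():
            for site in find_seed_sites(useq, mseq, gene_id, mature_id):
                rows.append(
                    {
                        "mature_id": mature_id,
                        "gene_id": gene_id,
                        "site_type": site.site_type,
                        "utr_start": site.utr_start,
                        "utr_end": site.utr_end,
                    }
                )
    table = pd.DataFrame(
        rows, columns=["mature_id", "gene_id", "site_type", "utr_start", "utr_end"]
    )
    logger.info(
        "seed scan: %d sites across %d miRNA-gene pairs",
        len(table),
        table.groupby(["mature_id", "gene_id"]).ngroups if len(table) else 0,
    )
    return table


def anticorrelation(mirna_expr: np.ndarray, gene_expr: np.ndarray) -> float:
    """Pearson correlation between matched miRNA and gene profiles.

    Returns NaN (pair excluded) for constant vectors; raises on length
    mismatch or fewer than 3 points.
    """
    x = np.asarray(mirna_expr, dtype=float)
    y = np.asarray(gene_expr, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"profile length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 matched conditions")
    if x.std() == 0.0 or y.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _condition_means(values: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Feature x (tissue, age) mean profile from a replicate-level matrix."""
    keys = {}
    for sid, row in samples.iterrows():
        keys.setdefault((row["tissue"], row["age"]), []).append(sid)
    cols = pd.MultiIndex.from_tuples(list(keys), names=["tissue", "age"])
    out = pd.DataFrame(index=values.index, columns=cols, dtype=float)
    for key, sids in keys.items():
        out[key] = values[sids].mean(axis=1)
    return out


def pairwise_pcc(mirna_prof: pd.DataFrame, gene_prof: pd.DataFrame) -> pd.DataFrame:
    """All miRNA x gene Pearson correlations over matched condition columns.

    Rows with zero variance yield NaN columns/rows (excluded downstream).
    """
    common = [c for c in mirna_prof.columns if c in gene_prof.columns]
    if len(common) < 3:
        raise ValueError("need at least 3 shared conditions for correlation")
    M = mirna_prof[common].to_numpy(dtype=float)
    G = gene_prof[common].to_numpy(dtype=float)
    k = len(common)

    def standardise(a: np.ndarray) -> np.ndarray:
        mu = a.mean(axis=1, keepdims=True)
        sd = a.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (a - mu) / sd
        z[np.repeat(sd == 0, a.shape[1], axis=1)] = np.nan
        return z

    C = standardise(M) @ standardise(G).T / k
    return pd.DataFrame(C, index=mirna_prof.index, columns=gene_prof.index)


def call_targets(
    mirna_values: pd.DataFrame,
    mirna_samples: pd.DataFrame,
    mrna_values: pd.DataFrame,
    mrna_samples: pd.DataFrame,
    sites: pd.DataFrame,
    mirna_detection: pd.DataFrame,
    pitt_table: pd.DataFrame,
    cfg: AnalysisConfig | None = None,
    restrict_mirnas=None,
    profile: str = "condition_means",
) -> pd.DataFrame:
    """Anti-correlation + seed-site target calls with autonomy labels.

    ``mirna_values`` should be the quantile-normalised log2 TPM matrix;
    ``mrna_values`` is the pre-normalised gene matrix.  With the default
    ``profile="condition_means"`` replicates are averaged into tissue-by-age
    condition means before the correlation (the age/tissue-level contrast);
    ``profile="replicates"`` correlates the replicate-matched samples
    directly.  ``mirna_detection`` is the group-level E table; a gene is
    considered expressed in a condition when its mean exceeds the configured
    mRNA threshold.  One row per (mature_id, gene_id, tissue, age).
    """
    cfg = cfg or AnalysisConfig()
    mirna_prof = _condition_means(mirna_values, mirna_samples)
    gene_prof = _condition_means(mrna_values, mrna_samples)
    if profile == "condition_means":
        pcc = pairwise_pcc(mirna_prof, gene_prof)
    elif profile == "replicates":
        mkey = mirna_samples.apply(
            lambda r: (r["tissue"], r["age"], r["replicate"]), axis=1
        )
        gkey = mrna_samples.apply(
            lambda r: (r["tissue"], r["age"], r["replicate"]), axis=1
        )
        m_by_key = mirna_values.copy()
        m_by_key.columns = pd.MultiIndex.from_tuples(mkey)
        g_by_key = mrna_values.copy()
        g_by_key.columns = pd.MultiIndex.from_tuples(gkey)
        pcc = pairwise_pcc(m_by_key, g_by_key)
    else:
        raise ValueError(f"unknown profile mode {profile!r}")
    gene_expressed = gene_prof > cfg.mrna_detection_threshold

    pair_sites = sites.groupby(["mature_id", "gene_id"])["site_type"].agg(
        lambda s: tuple(sorted(set(s)))
    )
    conditions = [c for c in mirna_detection.columns if c in gene_expressed.columns]
    rows = []
    for (mature_id, gene_id), site_types in pair_sites.items():
        if restrict_mirnas is not None and mature_id not in restrict_mirnas:
            continue
        if mature_id not in pcc.index or gene_id not in pcc.columns:
            continue
        r = pcc.loc[mature_id, gene_id]
        if not np.isfinite(r) or r >= cfg.pcc_threshold:
            continue
        for (tissue, age) in conditions:
            if not mirna_detection.loc[mature_id, (tissue, age)]:
                continue
            if not gene_expressed.loc[gene_id, (tissue, age)]:
                continue
            is_pitt = bool(
                mature_id in pitt_table.index
                and (tissue, age) in pitt_table.columns
                and pitt_table.loc[mature_id, (tissue, age)]
            )
            rows.append(
                {
                    "mature_id": mature_id,
                    "gene_id": gene_id,
                    "tissue": tissue,
                    "age": age,
                    "pcc": float(r),
                    "site_types": ",".join(site_types),
                    "autonomy": "non_autonomous" if is_pitt else "autonomous",
                }
            )
    calls = pd.DataFrame(
        rows,
        columns=["mature_id", "gene_id", "tissue", "age", "pcc", "site_types", "autonomy"],
    )
    logger.info(
        "target calling: %d calls over %d miRNA-gene pairs (%d non-autonomous)",
        len(calls),
        calls.groupby(["mature_id", "gene_id"]).ngroups if len(calls) else 0,
        int((calls["autonomy"] == "non_autonomous").sum()) if len(calls) else 0,
    )
    return calls


def genage_fraction(calls: pd.DataFrame, genage: set[str]) -> tuple[float, pd.DataFrame]:
    """Fraction of unique target genes annotated in the ageing-gene list."""
    genes = sorted(set(calls["gene_id"]))
    if not genes:
        logger.warning("empty target set; ageing-gene fraction undefined")
        return float("nan"), pd.DataFrame(columns=["gene_id", "genage"])
    flags = pd.DataFrame({"gene_id": genes, "genage": [g in genage for g in genes]})
    return float(flags["genage"].mean()), flags


def category_enrichment(
    target_genes: set[str],
    background_genes: set[str],
    annotation: pd.DataFrame,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher exact over-representation per category at each level.

    For every label at Category1/2/3, the 2x2 table contrasts category
    membership between target genes and the background (which must contain
    the targets).  Raw p < p_threshold marks significance, matching the
    unadjusted convention; a Benjamini-Hochberg FDR column is added.
    """
    if not target_genes <= background_genes:
        raise ValueError("background must contain all target genes")
    annot = annotation[annotation["gene_id"].isin(background_genes)]
    n_target = len(target_genes)
    n_bg = len(background_genes)
    rows = []
    for level in ("Category1", "Category2", "Category3"):
        for label, sub in annot.groupby(level):
            members = set(sub["gene_id"])
            a = len(target_genes & members)
            b = n_target - a
            c = len(members) - a
            d = (n_bg - n_target) - c
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            rows.append(
                {
                    "level": level,
                    "category": label,
                    "n_target_in": a,
                    "n_target_out": b,
                    "n_background_in": c,
                    "n_background_out": d,
                    "p": float(p),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "level",
            "category",
            "n_target_in",
            "n_target_out",
            "n_background_in",
            "n_background_out",
            "p",
        ],
    )
    if len(out):
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["p"] < p_threshold
    else:
        out["fdr"] = []
        out["significant"] = []
    return out
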