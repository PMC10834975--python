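"""Calibration and planted-truth recovery experiments.

These routines score the pipeline against the synthetic generator's known
truth and against statistical nominal rates; they back both the test suite
and the reproduction script.  Problem sizes are arguments so callers can
trade Monte-Carlo error against runtime.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from . import age_de, ev, normalize, pitt, targets as targets_mod
from .config import OTHER_SOURCE, AnalysisConfig
from .simulate import GeneratorConfig, generate

logger = logging.getLogger("mirflux")


# ---------------------------------------------------------------------------
# type-I calibration of the Box-Cox t-test
# ---------------------------------------------------------------------------

def type_i_calibration(
    n_datasets: int = 100, n_mirnas: int = 200, seed: int = 0
) -> dict:
    """Fraction of null-generator tests significant at p < 0.05.

    One tissue, no planted age effect: every p < 0.05 call is a false
    positive, so the pooled significant fraction estimates the test's
    type-I error rate.
    """
    cfg = AnalysisConfig()
    n_sig = n_tests = 0
    for d in range(n_datasets):
        gen = GeneratorConfig(
            n_tissues=1,
            n_mirnas=n_mirnas,
            n_genes=1,
            frac_age_dependent=0.0,
            frac_transported=0.0,
            frac_target_genes=0.0,
            seed=seed + d,
        )
        ds = generate(gen)
        tpm = normalize.compute_tpm(ds.tissue_counts)
        detection = normalize.call_detection_reads(
            ds.tissue_counts, cfg.detection_read_threshold
        )
        _, de = age_de.call_age_demirs(tpm, detection, cfg, mode="tissue")
        n_sig += int((de["p"] < cfg.p_threshold).sum())
        n_tests += len(de)
    frac = n_sig / n_tests if n_tests else float("nan")
    logger.info("type-I calibration: %d/%d significant (%.4f)", n_sig, n_tests, frac)
    return {"fraction_significant": frac, "n_tests": n_tests}


# ---------------------------------------------------------------------------
# permutation-z calibration
# ---------------------------------------------------------------------------

def _draw_null_network(
    rng: np.random.Generator, n_mirnas: int, tissues, p_other: float = 0.1
) -> pitt.TraffickingNetwork:
    """A network drawn from the permutation test's own null.

    Per miRNA: with probability ``p_other`` the source is external; else a
    source-set size of 1-3 (p = .5/.3/.2); receiver-set size 1-2; disjoint
    uniform subsets of the tissues.
    """
    tissues = tuple(tissues)
    k = len(tissues)
    sources: dict[str, frozenset] = {}
    receivers: dict[str, frozenset] = {}
    for i in range(n_mirnas):
        m = f"m{i:03d}"
        if rng.random() < p_other:
            s = 0
        else:
            s = int(rng.choice([1, 2, 3], p=[0.5, 0.3, 0.2]))
        r = int(rng.integers(1, 3))
        perm = rng.permutation(k)
        S = frozenset(tissues[j] for j in perm[:s])
        R = frozenset(tissues[j] for j in perm[s : s + r])
        sources[m], receivers[m] = S, R
    return pitt.network_from_sets(sources, receivers, tissues, "D1")


def permutation_z_calibration(
    n_datasets: int = 100,
    n_perm: int = 200,
    n_mirnas: int = 60,
    seed: int = 0,
) -> dict:
    """Tail rate of |z| > 1.96 when the observed network is itself null."""
    from .config import DEFAULT_TISSUES

    rng = np.random.default_rng(seed)
    n_tail = n_edges = 0
    for _ in range(n_datasets):
        net = _draw_null_network(rng, n_mirnas, DEFAULT_TISSUES)
        tested = pitt.permutation_flow_test(net, n_perm=n_perm, rng=rng)
        z = tested["z"].to_numpy()
        valid = np.isfinite(z)
        n_tail += int((np.abs(z[valid]) > 1.96).sum())
        n_edges += int(valid.sum())
    rate = n_tail / n_edges if n_edges else float("nan")
    logger.info("permutation-z calibration: %d/%d edges in tail (%.4f)", n_tail, n_edges, rate)
    return {"tail_rate": rate, "n_edges": n_edges}


# ---------------------------------------------------------------------------
# noiseless exact recovery
# ---------------------------------------------------------------------------

def noiseless_recovery(seed: int = 0) -> dict:
    """Exact PITT and trafficking-edge recovery on a noiseless dataset."""
    cfg = AnalysisConfig()
    ds = generate(GeneratorConfig(noiseless=True, seed=seed))
    detection = normalize.call_detection_reads(
        ds.tissue_counts, cfg.detection_read_threshold
    )
    t_mature = ds.transcription_map.to_mature(ds.annotation)
    e_calls = pitt.expression_calls(detection, cfg.tissues)
    pitt_set, _ = pitt.classify_pitt(e_calls, t_mature)

    truth_set = ds.truth.transported_set
    truth_edges: dict[str, set[tuple[str, str]]] = {a: set() for a in cfg.ages}
    single_source_edges: dict[str, set[tuple[str, str]]] = {a: set() for a in cfg.ages}
    for m, S, R, a in ds.truth.transport_events:
        for s in S:
            for r in R:
                truth_edges[a].add((s, r))
                if len(S) == 1:
                    single_source_edges[a].add((s, r))

    recovered: dict[str, set[tuple[str, str]]] = {}
    for age in cfg.ages:
        net = pitt.build_trafficking_network(e_calls, t_mature, age)
        recovered[age] = {
            (row["source"], row["target"]) for _, row in net.edges.iterrows()
        }
    edges_superset = all(truth_edges[a] <= recovered[a] for a in cfg.ages)
    edges_equal = all(recovered[a] == truth_edges[a] for a in cfg.ages)
    return {
        "pitt_exact": pitt_set == truth_set,
        "n_pitt": len(pitt_set),
        "n_truth": len(truth_set),
        "edges_superset_of_truth": edges_superset,
        "edges_equal_truth": edges_equal,
    }


# ---------------------------------------------------------------------------
# parameter recovery at generator defaults
# ---------------------------------------------------------------------------

def recover_one(seed: int) -> dict:
    """Score one default-parameter dataset against its planted truth."""
    cfg = AnalysisConfig()
    ds = generate(GeneratorConfig(seed=seed))
    truth = ds.truth

    tpm = normalize.compute_tpm(ds.tissue_counts)
    qnorm = normalize.log2_and_quantile_normalize(tpm, cfg.pseudocount)
    detection = normalize.call_detection_reads(
        ds.tissue_counts, cfg.detection_read_threshold
    )
    demirs, _ = age_de.call_age_demirs(tpm, detection, cfg, mode="tissue")
    planted = truth.age_dependent_set
    demir_recall = (
        len(planted & demirs.union) / len(planted) if planted else float("nan")
    )

    t_mature = ds.transcription_map.to_mature(ds.annotation)
    e_calls = pitt.expression_calls(detection, cfg.tissues)
    pitt_set, pitt_table = pitt.classify_pitt(e_calls, t_mature)
    pitt_precision = (
        len(pitt_set & truth.transported_set) / len(pitt_set)
        if pitt_set
        else float("nan")
    )

    umi_detection = normalize.call_detection_umi(
        ds.umi_counts, cfg.detection_umi_sum_threshold
    )
    rel = ev.relative_abundance(ds.umi_counts, umi_detection)
    loading = ev.loading_ratio(rel, cfg)
    joint = loading.index[loading["ratio_d1"].notna()]
    rho = stats.spearmanr(
        loading.loc[joint, "ratio_d1"],
        truth.sorting_weights.loc[joint, "D1"],
    ).statistic

    sites = targets_mod.build_site_table(ds.utr_seqs, ds.mirna_seqs)
    calls = targets_mod.call_targets(
        qnorm.values,
        qnorm.samples,
        ds.mrna_values,
        ds.mrna_samples,
        sites,
        e_calls,
        pitt_table,
        cfg,
    )
    called_pairs = set(zip(calls["mature_id"], calls["gene_id"]))
    planted_pairs = set(truth.target_pairs)
    sensitivity = (
        len(called_pairs & planted_pairs) / len(planted_pairs)
        if planted_pairs
        else float("nan")
    )
    fdr = (
        len(called_pairs - planted_pairs) / len(called_pairs)
        if called_pairs
        else 0.0
    )
    return {
        "age_demir_recall": demir_recall,
        "pitt_precision": pitt_precision,
        "loading_spearman": float(rho),
        "target_sensitivity": sensitivity,
        "target_fdr": fdr,
    }


def parameter_recovery(n_seeds: int = 20, seed0: int = 0) -> pd.DataFrame:
    """Recovery scores over seeded datasets at generator defaults."""
    rows = [recover_one(seed0 + i) for i in range(n_seeds)]
    df = pd.DataFrame(rows)
    logger.info("parameter recovery means:\n%s", df.mean().to_string())
    return df
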