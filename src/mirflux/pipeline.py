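"""End-to-end orchestration and summary reports.

``run_all`` chains the stages on a directory of input files (the layout
written by :func:`mirflux.simulate.write_fixture`): normalisation and
detection, per-tissue differential expression, PITT classification and the
trafficking networks per age, the EV/worm loading-ratio analysis, and
target inference with autonomy partitioning and category enrichment.  All
reports are TSV/JSON; a machine-readable run manifest records the config,
input file hashes and per-stage row counts.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import age_de, ev, normalize, pitt, targets as targets_mod
from .config import AnalysisConfig
from .datatypes import ExpressionMatrix
from .io import (
    read_category_annotation,
    read_expression_matrix,
    read_fasta,
    read_gene_list,
    read_mirna_annotation,
    read_sample_sheet,
    read_transcription_map,
)

logger = logging.getLogger("mirflux")


# ---------------------------------------------------------------------------
# overlap reports
# ---------------------------------------------------------------------------

def overlap_report(sets: dict[str, set]) -> pd.DataFrame:
    """Exclusive-region counts for every non-empty combination of named sets.

    One row per combination: the members belonging to exactly those sets
    (Venn regions), plus the plain intersection size of the combination.
    """
    if len(sets) < 2:
        raise ValueError("overlap_report needs at least 2 sets")
    names = list(sets)
    union = set().union(*sets.values())
    rows = []
    for k in range(1, len(names) + 1):
        for combo in itertools.combinations(names, k):
            inter = set.intersection(*(sets[n] for n in combo))
            others = union - set().union(*(sets[n] for n in names if n not in combo)) \
                if k < len(names) else union
            exclusive = inter & others if k < len(names) else inter
            rows.append(
                {
                    "combination": "&".join(combo),
                    "k": k,
                    "n_exclusive": len(exclusive),
                    "n_intersection": len(inter),
                }
            )
    return pd.DataFrame(rows, columns=["combination", "k", "n_exclusive", "n_intersection"])


def shared_set_decay(sets: dict[str, set]) -> pd.DataFrame:
    """How many members are shared by at least k of the named sets.

    Non-increasing in k by construction (the share of a union shrinks as
    more sets must agree).
    """
    union = set().union(*sets.values()) if sets else set()
    counts = {m: sum(m in s for s in sets.values()) for m in union}
    rows = [
        {"k": k, "n_shared_by_at_least_k": sum(1 for v in counts.values() if v >= k)}
        for k in range(1, len(sets) + 1)
    ]
    return pd.DataFrame(rows, columns=["k", "n_shared_by_at_least_k"])


def overlap_percentage(subset_of: set, against: set) -> float:
    """|A intersection B| / |A| as a percentage (A = ``against``)."""
    if not against:
        return float("nan")
    return 100.0 * len(set(subset_of) & set(against)) / len(against)


# ---------------------------------------------------------------------------
# manifest helpers
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------

INPUT_FILES = {
    "tissue_counts": "tissue_counts.tsv",
    "tissue_samples": "tissue_samples.tsv",
    "umi_counts": "umi_counts.tsv",
    "umi_samples": "umi_samples.tsv",
    "mrna_expression": "mrna_expression.tsv",
    "mrna_samples": "mrna_samples.tsv",
    "mirna_mature": "mirna_mature.fa",
    "gene_utr": "gene_utr.fa",
    "transcription_map": "transcription_map.tsv",
    "mirna_annotation": "mirna_annotation.tsv",
    "genage": "genage.tsv",
    "wormcat": "wormcat.tsv",
}


def run_all(
    input_dir,
    out_dir,
    cfg: AnalysisConfig | None = None,
    n_perm: int | None = None,
    seed: int | None = None,
) -> dict:
    """Run every stage on an input directory; write reports; return results.

    Raises with the failing stage named; outputs written before a failure
    keep a ``.partial`` suffix.
    """
    cfg = cfg or AnalysisConfig()
    if n_perm is not None:
        cfg.n_permutations = n_perm
    if seed is not None:
        cfg.rng_seed = seed
    inp = Path(input_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / f"{name}.partial"
        df.to_csv(path, sep="\t", index=index)
        written.append(path)

    def finalise() -> None:
        for path in written:
            path.rename(path.with_name(path.name.removesuffix(".partial")))

    stage = "load_inputs"
    results: dict = {}
    try:
        paths = {k: inp / v for k, v in INPUT_FILES.items()}
        missing = [str(p) for p in paths.values() if not p.exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")

        annotation = read_mirna_annotation(paths["mirna_annotation"])
        counts = read_expression_matrix(paths["tissue_counts"], paths["tissue_samples"], cfg)
        tmap = read_transcription_map(
            paths["transcription_map"], cfg, genes=annotation.table["gene_id"].unique()
        )

        stage = "normalize_detect"
        tpm = normalize.compute_tpm(counts)
        qnorm = normalize.log2_and_quantile_normalize(tpm, cfg.pseudocount)
        detection = normalize.call_detection_reads(
            counts, cfg.detection_read_threshold, cfg.detection_group_rule
        )
        qc = normalize.ordination_qc(qnorm)
        emit(qc["pca_coordinates"], "pca.tsv", index=True)
        emit(qc["pearson_matrix"], "corr.tsv", index=True)
        emit(detection.per_group.astype(int), "detection_group.tsv", index=True)
        results["n_detected"] = int(detection.per_group.any(axis=1).sum())

        stage = "age_de"
        demirs, de = age_de.call_age_demirs(tpm, detection, cfg, mode="tissue")
        emit(de, "de_tissue.tsv")
        results["age_demirs"] = demirs
        results["n_age_demirs"] = len(demirs.union)
        tissue_sets = {
            t: demirs.tissue_set(t) for t in demirs.per_tissue
        }
        if len(tissue_sets) >= 2:
            emit(overlap_report(tissue_sets), "age_demir_overlap.tsv")
            emit(shared_set_decay(tissue_sets), "age_demir_shared_decay.tsv")

        stage = "pitt_network"
        t_mature = tmap.to_mature(annotation)
        e_calls = pitt.expression_calls(detection, cfg.tissues)
        pitt_set, pitt_table = pitt.classify_pitt(e_calls, t_mature)
        emit(pitt_table.astype(int), "pitt.tsv", index=True)
        results["pitt_set"] = pitt_set
        results["n_pitt"] = len(pitt_set)
        results["pitt_age_demir_overlap_pct"] = overlap_percentage(
            demirs.union, pitt_set
        )
        results["n_pitt_age_demirs"] = len(pitt_set & demirs.union)

        edge_tables = []
        rng = np.random.default_rng(cfg.rng_seed)
        for age in cfg.ages:
            net = pitt.build_trafficking_network(e_calls, t_mature, age)
            tested = pitt.permutation_flow_test(net, cfg.n_permutations, rng=rng)
            tested.insert(0, "age", age)
            tested["mirnas"] = tested["mirnas"].map(",".join)
            edge_tables.append(tested)
        edges = pd.concat(edge_tables, ignore_index=True)
        emit(edges, "network_edges.tsv")
        results["network_edges"] = edges

        e_by_rep = pitt.replicate_expression_calls(detection, counts.samples, cfg.tissues)
        flows = pitt.flow_summary(e_by_rep, t_mature, cfg.ages)
        emit(flows, "flows_replicate.tsv")

        stage = "ev_sorting"
        umi = read_expression_matrix(paths["umi_counts"], paths["umi_samples"], cfg)
        umi_detection = normalize.call_detection_umi(umi, cfg.detection_umi_sum_threshold)
        rel = ev.relative_abundance(umi, umi_detection)
        loading = ev.loading_ratio(rel, cfg)
        emit(loading, "ev_loading.tsv", index=True)
        results["loading_table"] = loading
        results["secretion_counts"] = (
            loading["secretion_class"].value_counts().to_dict()
        )
        ev_cols = [c for c in umi_detection.per_group.columns if c[0] == "EV"]
        results["n_ev_detected"] = int(umi_detection.per_group[ev_cols].any(axis=1).sum())
        results["n_pitt_in_ev"] = len(
            pitt_set & set(umi_detection.per_group.index[
                umi_detection.per_group[ev_cols].any(axis=1)
            ])
        )

        rel_rep = umi.with_values(
            umi.values / umi.values.sum(axis=0), "relative_abundance"
        )
        ev_demirs, ev_de = age_de.call_age_demirs(
            rel_rep, umi_detection, cfg, mode="compartment"
        )
        emit(ev_de, "de_compartment.tsv")
        results["ev_de"] = ev_de

        stage = "target_autonomy"
        mirna_seqs = read_fasta(paths["mirna_mature"])
        utr_seqs = read_fasta(paths["gene_utr"])
        sites = targets_mod.build_site_table(utr_seqs, mirna_seqs)
        mrna_samples = read_sample_sheet(paths["mrna_samples"], cfg)
        mrna_values = pd.read_csv(paths["mrna_expression"], sep="\t", index_col=0)
        calls = targets_mod.call_targets(
            qnorm.values,
            qnorm.samples,
            mrna_values,
            mrna_samples,
            sites,
            pitt.expression_calls(detection, cfg.tissues),
            pitt_table,
            cfg,
        )
        emit(calls, "targets.tsv")
        results["target_calls"] = calls

        autonomy_rows = []
        for (tissue, age), sub in calls.groupby(["tissue", "age"]):
            n = len(sub)
            n_na = int((sub["autonomy"] == "non_autonomous").sum())
            autonomy_rows.append(
                {
                    "tissue": tissue,
                    "age": age,
                    "n_targets": n,
                    "n_non_autonomous": n_na,
                    "pct_non_autonomous": 100.0 * n_na / n if n else float("nan"),
                }
            )
        autonomy = pd.DataFrame(
            autonomy_rows,
            columns=["tissue", "age", "n_targets", "n_non_autonomous", "pct_non_autonomous"],
        )
        emit(autonomy, "autonomy.tsv")

        genage = read_gene_list(paths["genage"])
        demir_calls = calls[calls["mature_id"].isin(demirs.union)]
        frac, flags = targets_mod.genage_fraction(demir_calls, genage)
        results["genage_fraction"] = frac
        emit(flags, "genage_targets.tsv")

        categories = read_category_annotation(paths["wormcat"])
        # background: genes expressed in at least one tissue-age condition
        expressed_anywhere = (
            mrna_values.T.groupby(
                [mrna_samples["tissue"], mrna_samples["age"]]
            ).mean().T
            > cfg.mrna_detection_threshold
        ).any(axis=1)
        background = set(mrna_values.index[expressed_anywhere].astype(str))
        background |= set(demir_calls["gene_id"])
        target_genes = set(demir_calls["gene_id"])
        enrichment = targets_mod.category_enrichment(
            target_genes, background, categories, cfg.p_threshold
        )
        emit(enrichment, "enrichment.tsv")

        stage = "manifest"
        manifest = {
            "config": cfg.to_dict(),
            "seed": cfg.rng_seed,
            "inputs": {k: _sha256(p) for k, p in paths.items()},
            "row_counts": {
                "de_tissue": len(de),
                "pitt": len(pitt_table),
                "network_edges": len(edges),
                "ev_loading": len(loading),
                "targets": len(calls),
                "enrichment": len(enrichment),
            },
        }
        with open(out / "manifest.json.partial", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        written.append(out / "manifest.json.partial")
        finalise()
        results["manifest"] = manifest
        return results
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
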