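"""Synthetic data generator with planted ground truth.

Generates a complete dataset shaped like the tissue-resolved miRNA ageing
study: negative-binomial read counts for five somatic tissues at two adult
ages with three replicates, multinomially sampled UMI counts for whole-worm
and EV compartments, a promoter-activity (transcription) map, a matched
pre-normalised mRNA matrix, mature miRNA and 3'UTR sequences with planted
canonical seed sites, and annotation tables (miRNA curation, functional
categories, ageing genes).  Every planted effect is returned in a
:class:`TruthBundle` so each pipeline stage can be scored against known
truth.  All randomness flows from one seed.

What is planted
---------------
* transcription: each miRNA gene is transcribed in 1-3 random tissues;
* transport: a fraction of miRNAs additionally appear, at a configurable
  fraction of their source level, in disjoint receiver tissues;
* ageing: a fraction of miRNAs change ``age_effect_fold``-fold (up or down)
  between day 1 and day 8 wherever they are present;
* EV sorting: each miRNA carries a log-normal EV loading weight; subsets
  get their day-8 weight boosted or damped ``sorting_shift_fold``-fold,
  planting age-promoted / age-suppressed secretion;
* targets: a fraction of genes are anti-correlated with one miRNA across
  the tissue-by-age conditions and carry one planted 8mer site in their
  UTR; all other UTRs are scrubbed of accidental seed cores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DEFAULT_AGES, DEFAULT_TISSUES, AnalysisConfig
from .datatypes import (
    ExpressionMatrix,
    MirnaAnnotation,
    SampleMeta,
    TranscriptionMap,
    samples_frame,
)
from .io import (
    write_expression_matrix,
    write_fasta,
    write_mirna_annotation,
    write_sample_sheet,
    write_transcription_map,
)
from .targets import reverse_complement

logger = logging.getLogger("mirflux")

RNA = np.array(list("ACGU"))


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic dataset; defaults emulate the study design."""

    n_tissues: int = 5
    n_replicates: int = 3
    n_mirnas: int = 60
    n_genes: int = 300
    #: NB dispersion alpha: var = mu + alpha * mu^2 (size = 1/alpha).
    nb_dispersion: float = 0.1
    #: log-normal baseline of expected counts in a transcribed tissue.
    baseline_log_mean: float = float(np.log(300.0))
    baseline_log_sd: float = 1.0
    frac_age_dependent: float = 0.3
    age_effect_fold: float = 4.0
    frac_transported: float = 0.3
    #: receiver-tissue abundance as a fraction of the mean source level.
    transport_fraction: float = 0.2
    sorting_weight_log_sd: float = 1.0
    #: fractions of EV-loaded miRNAs whose day-8 sorting is boosted/damped.
    frac_sorting_promoted: float = 0.3
    frac_sorting_suppressed: float = 0.3
    sorting_shift_fold: float = 3.0
    #: anti-correlation strength (log2 units per SD of the miRNA profile).
    target_strength: float = 2.0
    frac_target_genes: float = 0.2
    umi_depth: int = 200_000
    utr_length: int = 200
    mirna_length: int = 22
    noiseless: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_age_dependent",
            "frac_transported",
            "frac_sorting_promoted",
            "frac_sorting_suppressed",
            "frac_target_genes",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.age_effect_fold <= 0 or self.sorting_shift_fold <= 0:
            raise ValueError("fold parameters must be positive")
        if self.frac_transported > 0 and self.n_tissues < 2:
            raise ValueError("transport requires at least 2 tissues")
        if self.n_tissues > len(DEFAULT_TISSUES):
            raise ValueError(f"at most {len(DEFAULT_TISSUES)} tissues supported")


@dataclass
class TruthBundle:
    """Planted ground truth for scoring the pipeline."""

    transcription_map: TranscriptionMap
    #: (mature_id, source tissue frozenset, receiver tissue frozenset, age)
    transport_events: list = field(default_factory=list)
    #: (mature_id, tissue, direction in {up, down})
    age_demir_truth: list = field(default_factory=list)
    #: mature x age EV sorting weights (relative; arbitrary common scale)
    sorting_weights: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: (mature_id, gene_id) planted target pairs
    target_pairs: list = field(default_factory=list)

    @property
    def transported_set(self) -> set[str]:
        return {m for m, _, _, _ in self.transport_events}

    @property
    def age_dependent_set(self) -> set[str]:
        return {m for m, _, _ in self.age_demir_truth}


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    tissue_counts: ExpressionMatrix
    umi_counts: ExpressionMatrix
    mrna_values: pd.DataFrame
    mrna_samples: pd.DataFrame
    mirna_seqs: dict
    utr_seqs: dict
    annotation: MirnaAnnotation
    transcription_map: TranscriptionMap
    genage: set
    categories: pd.DataFrame
    truth: TruthBundle


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(RNA, size=length))


def _unique_seed_mirnas(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """Random mature sequences with pairwise-distinct seed regions (pos 2-8)."""
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n:
        s = _random_seq(rng, length)
        if s[1:8] in seen:
            continue
        seen.add(s[1:8])
        seqs.append(s)
    return seqs


def _scrub_utr(
    rng: np.random.Generator,
    utr: list[str],
    cores: dict[str, str],
    keep: tuple[int, int] | None = None,
) -> None:
    """Mutate bases until no seed core matches outside the ``keep`` window.

    Operates in place on a list of characters; a match is destroyed by
    replacing one of its bases with a different random base, re-scanning
    until clean (a fresh match can appear at a mutated locus).
    """
    for _ in range(200):
        dirty = False
        s = "".join(utr)
        for core in cores.values():
            i = s.find(core)
            while i != -1:
                if keep is not None and keep[0] <= i and i + 6 <= keep[1]:
                    i = s.find(core, i + 1)
                    continue
                j = i + int(rng.integers(6))
                if keep is not None and keep[0] <= j < keep[1]:
                    j = i if i < keep[0] else i + 5
                old = utr[j]
                choices = [c for c in "ACGU" if c != old]
                utr[j] = choices[int(rng.integers(3))]
                dirty = True
                break
            if dirty:
                break
        if not dirty:
            return
    raise RuntimeError("UTR scrubbing did not converge")


def generate(cfg: GeneratorConfig | None = None) -> SyntheticDataset:
    """Generate one complete synthetic dataset; deterministic per seed."""
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    tissues = DEFAULT_TISSUES[: cfg.n_tissues]
    ages = DEFAULT_AGES
    nM, nG = cfg.n_mirnas, cfg.n_genes

    # -- identities and sequences ------------------------------------------
    genes = [f"mir-{i + 1:03d}" for i in range(nM)]
    arms = rng.choice(["3p", "5p"], size=nM)
    matures = [f"{g}-{a}" for g, a in zip(genes, arms)]
    mirna_seqs = dict(zip(matures, _unique_seed_mirnas(rng, nM, cfg.mirna_length)))
    cores = {m: reverse_complement(s[1:7]) for m, s in mirna_seqs.items()}

    annotation = MirnaAnnotation(
        pd.DataFrame(
            {
                "gene_id": genes,
                "family_id": [f"fam-{(i % max(1, nM // 2)) + 1:03d}" for i in range(nM)],
                "arm": arms,
                "conserved_in_mammals": rng.random(nM) < 0.5,
                "mature_sequence": [mirna_seqs[m] for m in matures],
            },
            index=pd.Index(matures, name="mature_id"),
        )
    )

    # -- transcription map --------------------------------------------------
    n_src = rng.choice([1, 2, 3], size=nM, p=[0.5, 0.3, 0.2])
    source_sets = [
        frozenset(rng.choice(tissues, size=min(k, len(tissues)), replace=False))
        for k in n_src
    ]
    columns = pd.MultiIndex.from_product([tissues, ages], names=["tissue", "age"])
    tmap_calls = pd.DataFrame(False, index=pd.Index(genes, name="gene"), columns=columns)
    for g, S in zip(genes, source_sets):
        for t in S:
            for a in ages:
                tmap_calls.loc[g, (t, a)] = True
    tmap = TranscriptionMap(calls=tmap_calls)

    # -- transport truth ----------------------------------------------------
    n_transported = int(round(cfg.frac_transported * nM))
    candidates = [i for i in range(nM) if len(source_sets[i]) < len(tissues)]
    transported_idx = sorted(
        rng.choice(candidates, size=min(n_transported, len(candidates)), replace=False)
    )
    receiver_sets: dict[int, frozenset] = {}
    transport_events = []
    for i in transported_idx:
        free = sorted(set(tissues) - source_sets[i])
        k = int(rng.integers(1, min(2, len(free)) + 1))
        R = frozenset(rng.choice(free, size=k, replace=False))
        receiver_sets[i] = R
        for a in ages:
            transport_events.append((matures[i], source_sets[i], R, a))

    # -- expected expression ------------------------------------------------
    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=nM)
    tissue_mod = rng.lognormal(0.0, 0.2, size=(nM, len(tissues)))

    n_aged = int(round(cfg.frac_age_dependent * nM))
    aged_idx = sorted(rng.choice(nM, size=n_aged, replace=False))
    directions = {i: ("up" if rng.random() < 0.5 else "down") for i in aged_idx}
    age_factor = np.ones(nM)
    for i, d in directions.items():
        age_factor[i] = cfg.age_effect_fold if d == "up" else 1.0 / cfg.age_effect_fold

    # mean[m, t, age]: source tissues at full level, receivers at a fraction
    mean = np.zeros((nM, len(tissues), len(ages)))
    for i in range(nM):
        src_level = baseline[i]
        for j, t in enumerate(tissues):
            level = 0.0
            if t in source_sets[i]:
                level = src_level * tissue_mod[i, j]
            elif t in receiver_sets.get(i, frozenset()):
                level = cfg.transport_fraction * src_level * tissue_mod[i, j]
            for k, a in enumerate(ages):
                f = age_factor[i] if a == "D8" else 1.0
                mean[i, j, k] = level * f

    age_demir_truth = []
    for i, d in directions.items():
        present = source_sets[i] | receiver_sets.get(i, frozenset())
        for t in present:
            age_demir_truth.append((matures[i], t, d))

    # -- tissue count matrix -------------------------------------------------
    size = 1.0 / cfg.nb_dispersion if cfg.nb_dispersion > 0 else np.inf
    metas, cols = [], {}
    for j, t in enumerate(tissues):
        for k, a in enumerate(ages):
            for r in range(1, cfg.n_replicates + 1):
                sid = f"{t}_{a}_r{r}"
                metas.append(SampleMeta(sid, t, a, r, "reads"))
                mu = mean[:, j, k]
                if cfg.noiseless:
                    # detection guaranteed: every present miRNA clears the read rule
                    counts = np.where(mu > 0, np.maximum(np.round(mu), 10), 0).astype(int)
                elif np.isfinite(size):
                    counts = np.where(
                        mu > 0,
                        rng.negative_binomial(size, size / (size + np.maximum(mu, 1e-9))),
                        0,
                    )
                else:  # nb_dispersion == 0: Poisson limit
                    counts = rng.poisson(mu)
                cols[sid] = counts
    tissue_counts = ExpressionMatrix(
        values=pd.DataFrame(cols, index=pd.Index(matures, name="mature_id")),
        samples=samples_frame(metas),
        scale="raw_count",
    )

    # -- whole-worm and EV UMI matrices --------------------------------------
    worm_share = mean.sum(axis=1)  # [miRNA x age]
    sorting = rng.lognormal(0.0, cfg.sorting_weight_log_sd, size=nM)
    n_promoted = int(round(cfg.frac_sorting_promoted * nM))
    n_suppressed = int(round(cfg.frac_sorting_suppressed * nM))
    shifted = rng.permutation(nM)
    promoted_idx = set(shifted[:n_promoted].tolist())
    suppressed_idx = set(shifted[n_promoted : n_promoted + n_suppressed].tolist())
    shift_d8 = np.ones(nM)
    for i in promoted_idx:
        shift_d8[i] = cfg.sorting_shift_fold
    for i in suppressed_idx:
        shift_d8[i] = 1.0 / cfg.sorting_shift_fold
    sorting_weights = pd.DataFrame(
        {"D1": sorting, "D8": sorting * shift_d8},
        index=pd.Index(matures, name="mature_id"),
    )

    metas, cols = [], {}
    for comp in ("Worm", "EV"):
        for k, a in enumerate(ages):
            share = worm_share[:, k].astype(float)
            if comp == "EV":
                share = share * sorting_weights[a].to_numpy()
            total = share.sum()
            if total <= 0:
                raise ValueError("degenerate configuration: empty compartment")
            p = share / total
            for r in range(1, cfg.n_replicates + 1):
                sid = f"{comp}_{a}_r{r}"
                metas.append(SampleMeta(sid, comp, a, r, "UMI"))
                if cfg.noiseless:
                    cols[sid] = np.round(p * cfg.umi_depth).astype(int)
                else:
                    cols[sid] = rng.multinomial(cfg.umi_depth, p)
    umi_counts = ExpressionMatrix(
        values=pd.DataFrame(cols, index=pd.Index(matures, name="mature_id")),
        samples=samples_frame(metas),
        scale="raw_count",
    )

    # -- mRNA matrix and target truth ----------------------------------------
    gene_ids = [f"gene-{i + 1:04d}" for i in range(nG)]
    n_targets = int(round(cfg.frac_target_genes * nG))
    target_gene_idx = sorted(rng.choice(nG, size=n_targets, replace=False))
    target_mirna_for_gene = {
        gi: int(rng.integers(nM)) for gi in target_gene_idx
    }
    target_pairs = [(matures[mi], gene_ids[gi]) for gi, mi in target_mirna_for_gene.items()]

    # miRNA condition profile on log2 scale (what the anti-correlation sees)
    log_prof = np.log2(mean.reshape(nM, -1) + 1.0)  # [miRNA x (tissue x age)]
    prof_sd = log_prof.std(axis=1, keepdims=True)
    prof_sd[prof_sd == 0] = 1.0
    z_prof = (log_prof - log_prof.mean(axis=1, keepdims=True)) / prof_sd

    n_cond = len(tissues) * len(ages)
    base_g = rng.normal(6.0, 1.0, size=nG)
    cond_expr = np.empty((nG, n_cond))
    for gi in range(nG):
        if gi in target_mirna_for_gene:
            mi = target_mirna_for_gene[gi]
            cond_expr[gi] = (
                base_g[gi]
                - cfg.target_strength * z_prof[mi]
                + rng.normal(0.0, 0.3, size=n_cond)
            )
        else:
            cond_expr[gi] = base_g[gi] + rng.normal(0.0, 1.0, size=n_cond)

    metas, cols = [], {}
    c = 0
    for j, t in enumerate(tissues):
        for k, a in enumerate(ages):
            for r in range(1, cfg.n_replicates + 1):
                sid = f"mrna_{t}_{a}_r{r}"
                metas.append(SampleMeta(sid, t, a, r, "reads"))
                noise = 0.0 if cfg.noiseless else rng.normal(0.0, 0.2, size=nG)
                cols[sid] = cond_expr[:, c] + noise
            c += 1
    mrna_samples = samples_frame(metas)
    mrna_values = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))

    # -- UTRs with planted sites ---------------------------------------------
    utr_seqs: dict[str, str] = {}
    for gi, g in enumerate(gene_ids):
        utr = list(_random_seq(rng, cfg.utr_length))
        keep = None
        if gi in target_mirna_for_gene:
            mi = target_mirna_for_gene[gi]
            site = reverse_complement(mirna_seqs[matures[mi]][1:8]) + "A"  # 8mer
            pos = int(rng.integers(5, cfg.utr_length - len(site) - 5))
            utr[pos : pos + len(site)] = list(site)
            keep = (pos, pos + len(site))
        _scrub_utr(rng, utr, cores, keep=keep)
        utr_seqs[g] = "".join(utr)

    # -- annotations ----------------------------------------------------------
    genage = set(np.array(gene_ids)[rng.random(nG) < 0.15])
    cat1 = [f"Process-{i}" for i in range(1, 9)]
    c1 = rng.choice(cat1, size=nG)
    c2 = [f"{c}:sub{int(rng.integers(1, 3))}" for c in c1]
    c3 = [f"{c}:leaf{int(rng.integers(1, 3))}" for c in c2]
    categories = pd.DataFrame(
        {"gene_id": gene_ids, "Category1": c1, "Category2": c2, "Category3": c3}
    )

    truth = TruthBundle(
        transcription_map=tmap,
        transport_events=transport_events,
        age_demir_truth=age_demir_truth,
        sorting_weights=sorting_weights,
        target_pairs=target_pairs,
    )
    logger.info(
        "synthetic dataset: %d miRNAs (%d transported, %d age-dependent), %d genes "
        "(%d target pairs)",
        nM,
        len(transported_idx),
        len(aged_idx),
        nG,
        len(target_pairs),
    )
    return SyntheticDataset(
        config=cfg,
        tissue_counts=tissue_counts,
        umi_counts=umi_counts,
        mrna_values=mrna_values,
        mrna_samples=mrna_samples,
        mirna_seqs=mirna_seqs,
        utr_seqs=utr_seqs,
        annotation=annotation,
        transcription_map=tmap,
        genage=genage,
        categories=categories,
        truth=truth,
    )


def write_fixture(ds: SyntheticDataset, out_dir, force: bool = False) -> dict[str, Path]:
    """Write every file the CLI consumes, plus truth tables for harnesses."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (use force=True to overwrite)")

    paths: dict[str, Path] = {}

    def p(name: str) -> Path:
        paths[name] = out / name
        return paths[name]

    write_expression_matrix(ds.tissue_counts, p("tissue_counts.tsv"), p("tissue_samples.tsv"))
    write_expression_matrix(ds.umi_counts, p("umi_counts.tsv"), p("umi_samples.tsv"))
    mrna = ds.mrna_values.copy()
    mrna.index.name = "gene_id"
    mrna.to_csv(p("mrna_expression.tsv"), sep="\t")
    write_sample_sheet(ds.mrna_samples, p("mrna_samples.tsv"))
    write_fasta(ds.mirna_seqs, p("mirna_mature.fa"))
    write_fasta(ds.utr_seqs, p("gene_utr.fa"))
    write_transcription_map(ds.transcription_map, p("transcription_map.tsv"))
    write_mirna_annotation(ds.annotation, p("mirna_annotation.tsv"))
    pd.DataFrame({"gene_id": sorted(ds.genage)}).to_csv(
        p("genage.tsv"), sep="\t", index=False
    )
    ds.categories.to_csv(p("wormcat.tsv"), sep="\t", index=False)

    truth = ds.truth
    pd.DataFrame(
        [
            {
                "mature_id": m,
                "sources": ",".join(sorted(S)),
                "receivers": ",".join(sorted(R)),
                "age": a,
            }
            for m, S, R, a in truth.transport_events
        ]
    ).to_csv(p("truth_transport.tsv"), sep="\t", index=False)
    pd.DataFrame(
        truth.age_demir_truth, columns=["mature_id", "tissue", "direction"]
    ).to_csv(p("truth_age_demirs.tsv"), sep="\t", index=False)
    sw = truth.sorting_weights.copy()
    sw.index.name = "mature_id"
    sw.to_csv(p("truth_sorting_weights.tsv"), sep="\t")
    pd.DataFrame(truth.target_pairs, columns=["mature_id", "gene_id"]).to_csv(
        p("truth_target_pairs.tsv"), sep="\t", index=False
    )
    logger.info("fixture written to %s (%d files)", out, len(paths))
    return paths
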