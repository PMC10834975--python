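"""Readers and writers for the pipeline's file formats.

Everything on disk is TSV with a header row (decimal point, no thousands
separators) or plain FASTA, so round-trips are bit-exact for integer counts
and reproducible to float precision otherwise.

Formats
-------
count table     feature id in the first column, one column per sample.
sample sheet    columns: sample_id, tissue, age, replicate, count_unit.
transcription   long format, columns: gene, tissue, age, call (0/1).
annotation      columns: mature_id, gene_id, family_id, arm,
                conserved_in_mammals, mature_sequence (optional).
FASTA           mature miRNAs (T normalised to U) and gene 3'UTRs
                (also normalised to the RNA alphabet).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import AnalysisConfig
from .datatypes import (
    ExpressionMatrix,
    MirnaAnnotation,
    SchemaError,
    TranscriptionMap,
    validate_samples,
)

logger = logging.getLogger("mirflux")


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_sample_sheet(path, config: AnalysisConfig | None = None) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in sheet.columns:
        raise SchemaError(f"{path}: sample sheet needs a 'sample_id' column")
    sheet = sheet.set_index("sample_id")
    return validate_samples(sheet, config)


def read_expression_matrix(
    path, meta, config: AnalysisConfig | None = None, scale: str = "raw_count"
) -> ExpressionMatrix:
    """Read a count table plus its sample sheet into an ExpressionMatrix.

    Column order follows the sample sheet; the table may list columns in any
    order but must contain exactly the sheet's sample ids.
    """
    samples = meta if isinstance(meta, pd.DataFrame) else read_sample_sheet(meta, config)
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    if table.index.duplicated().any():
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise SchemaError(f"{path}: duplicate feature ids {dups}")
    missing = [s for s in samples.index if s not in table.columns]
    extra = [c for c in table.columns if c not in samples.index]
    if missing or extra:
        raise SchemaError(
            f"{path}: sample sheet/column mismatch (missing {missing}, extra {extra})"
        )
    table = table[list(samples.index)]
    if (table.to_numpy() < 0).any() and scale in ("raw_count", "tpm", "relative_abundance"):
        raise ValueError(f"{path}: negative values in a {scale} matrix")
    em = ExpressionMatrix(values=table, samples=samples, scale=scale)
    logger.info("read %s: %d features x %d samples", path, em.n_features, em.n_samples)
    return em


def write_expression_matrix(em: ExpressionMatrix, path, meta_path=None) -> None:
    df = em.values.copy()
    df.index.name = df.index.name or "feature_id"
    df.to_csv(path, sep="\t")
    if meta_path is not None:
        write_sample_sheet(em.samples, meta_path)


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    out = samples.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# transcription map
# ---------------------------------------------------------------------------

def read_transcription_map(
    path, config: AnalysisConfig | None = None, genes=None
) -> TranscriptionMap:
    """Read a long-format promoter-activity table.

    Missing (gene, tissue, age) combinations default to False (no reporter
    signal) and are logged; unknown tissue or age labels raise.
    """
    cfg = config or AnalysisConfig()
    long = pd.read_csv(path, sep="\t", dtype={"gene": str})
    required = {"gene", "tissue", "age", "call"}
    if long.empty and not required.issubset(long.columns):
        logger.warning("%s: empty transcription map, all calls default to False", path)
        long = pd.DataFrame(columns=["gene", "tissue", "age", "call"])
    missing = required - set(long.columns)
    if missing:
        raise SchemaError(f"{path}: transcription map missing columns {sorted(missing)}")
    for label in long["tissue"].unique():
        cfg.check_tissue(label)
    for label in long["age"].unique():
        cfg.check_age(label)
    extra_genes = [] if genes is None else list(genes)
    all_genes = list(dict.fromkeys(extra_genes + list(long["gene"])))
    columns = pd.MultiIndex.from_product([cfg.tissues, cfg.ages], names=["tissue", "age"])
    calls = pd.DataFrame(False, index=pd.Index(all_genes, name="gene"), columns=columns)
    for _, row in long.iterrows():
        calls.loc[row["gene"], (row["tissue"], row["age"])] = bool(int(row["call"]))
    n_missing = int((calls.size) - len(long))
    if n_missing:
        logger.info(
            "%s: %d (gene, tissue, age) combinations absent, defaulted to False",
            path,
            n_missing,
        )
    return TranscriptionMap(calls=calls)


def write_transcription_map(tmap: TranscriptionMap, path, only_true: bool = False) -> None:
    rows = []
    for gene in tmap.calls.index:
        for (tissue, age) in tmap.calls.columns:
            call = bool(tmap.calls.loc[gene, (tissue, age)])
            if only_true and not call:
                continue
            rows.append((gene, tissue, age, int(call)))
    pd.DataFrame(rows, columns=["gene", "tissue", "age", "call"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_T2U = str.maketrans("Tt", "Uu")


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an id -> sequence mapping, normalised to RNA.

    T is accepted on input and converted to U; sequences are upper-cased.
    Duplicate ids and empty sequences are errors.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise SchemaError(f"{path}: duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).translate(_T2U).upper()
        if not seq:
            raise SchemaError(f"{path}: empty sequence for {rec.id!r}")
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------

def read_mirna_annotation(path) -> MirnaAnnotation:
    table = pd.read_csv(path, sep="\t", index_col="mature_id")
    if "conserved_in_mammals" in table.columns:
        table["conserved_in_mammals"] = table["conserved_in_mammals"].astype(bool)
    return MirnaAnnotation(table=table)


def write_mirna_annotation(annot: MirnaAnnotation, path) -> None:
    out = annot.table.copy()
    out.index.name = "mature_id"
    out["conserved_in_mammals"] = out["conserved_in_mammals"].astype(int)
    out.to_csv(path, sep="\t")


def read_gene_list(path, column: str = "gene_id") -> set[str]:
    """Read a one-column gene list (e.g. an ageing-gene annotation)."""
    df = pd.read_csv(path, sep="\t")
    if column not in df.columns:
        raise SchemaError(f"{path}: expected a {column!r} column")
    return set(df[column].astype(str))


def read_category_annotation(path) -> pd.DataFrame:
    """Read a three-level functional category table (gene_id, Category1..3)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "Category1", "Category2", "Category3"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: category table missing columns {sorted(missing)}")
    return df
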