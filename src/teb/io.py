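"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts and metadata travel as TSV; gene models as GTF (1-based inclusive,
``gene`` features with ``gene_id``/``gene_biotype`` attributes) or BED6
(0-based half-open); TADs as BED3+.  Internally all coordinates are 0-based
half-open.
"""

from __future__ import annotations

from pathlib import Path

import gffutils
import pandas as pd

from .experiment import GeneModel, TimeCourseExperiment, genes_to_frame

FLOAT_FMT = "%.6g"


# ----------------------------------------------------------------- counts/meta
def write_counts_tsv(expt: TimeCourseExperiment, path: str | Path) -> None:
    expt.counts.to_csv(path, sep="\t", index_label="gene_id")


def write_meta_tsv(expt: TimeCourseExperiment, path: str | Path) -> None:
    expt.meta.to_csv(path, sep="\t", index_label="sample_id")


def read_experiment(counts_path: str | Path, meta_path: str | Path) -> TimeCourseExperiment:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    counts.columns = counts.columns.astype(str)
    return TimeCourseExperiment(counts, meta)


def write_logexpr_tsv(expt: TimeCourseExperiment, path: str | Path) -> None:
    expt.require_logexpr().to_csv(
        path, sep="\t", index_label="gene_id", float_format=FLOAT_FMT
    )


# ----------------------------------------------------------------- gene models
def write_gtf(genes: pd.DataFrame, path: str | Path, source: str = "teb") -> None:
    """Write gene features as GTF; converts to 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for r in genes.itertuples(index=False):
            attrs = f'gene_id "{r.gene_id}"; gene_biotype "{r.biotype}";'
            fh.write(
                f"{r.chrom}\t{source}\tgene\t{r.start + 1}\t{r.end}\t.\t"
                f"{r.strand}\t.\t{attrs}\n"
            )


def read_gtf_genes(path: str | Path) -> pd.DataFrame:
    """Read gene features from a GTF into a gene table (0-based half-open)."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models = []
    for feat in db.features_of_type("gene"):
        biotype = feat.attributes.get("gene_biotype", ["other"])[0]
        models.append(
            GeneModel(
                feat.attributes["gene_id"][0],
                feat.seqid,
                feat.start - 1,
                feat.end,
                feat.strand,
                biotype,
            )
        )
    return genes_to_frame(models)


def write_bed6(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in genes.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\t0\t{r.strand}\n")


def read_bed6_genes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
    )
    models = [
        GeneModel(r.gene_id, r.chrom, int(r.start), int(r.end), r.strand)
        for r in df.itertuples(index=False)
    ]
    return genes_to_frame(models)


def read_tads_bed(path: str | Path) -> pd.DataFrame:
    """Read TAD intervals from BED3+ (extra columns ignored)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    if (df["start"] >= df["end"]).any():
        raise ValueError("TAD intervals must have start < end")
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
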