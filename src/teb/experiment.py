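"""Core containers for the 6-hourly embryoid-body time-course design.

The study design is a dense bulk RNA-seq time course: differentiating mouse
embryonic stem cells sampled every 6 hours from 0 to 120 h in biological
duplicate (21 time points x 2 replicates = 42 libraries).  Counts are held
gene x sample; most downstream statistics operate on the replicate-mean
log2 expression profile of each gene over the 21 time points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: biotypes treated as long noncoding for candidate selection and pair classes
LNCRNA_BIOTYPES = frozenset({"lincRNA", "antisense", "processed_transcript"})


@dataclass(frozen=True)
class SampleMeta:
    """One sequencing library: its collection time and replicate label."""

    sample_id: str
    time_hours: float
    replicate: str

    def __post_init__(self) -> None:
        if self.time_hours < 0:
            raise ValueError(f"negative time for sample {self.sample_id}")


@dataclass(frozen=True)
class GeneModel:
    """Genomic gene model; coordinates are 0-based half-open internally."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        """Strand-aware transcriptional start site."""
        return self.start if self.strand == "+" else self.end

    @property
    def is_lncrna(self) -> bool:
        return self.biotype in LNCRNA_BIOTYPES


def genes_to_frame(genes: Iterable[GeneModel]) -> pd.DataFrame:
    """Tabulate gene models; adds a strand-aware ``tss`` column."""
    rows = [
        (g.gene_id, g.chrom, g.start, g.end, g.strand, g.biotype, g.tss)
        for g in genes
    ]
    df = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "biotype", "tss"]
    )
    return df.set_index("gene_id", drop=False)


def frame_to_genes(df: pd.DataFrame) -> list[GeneModel]:
    return [
        GeneModel(r.gene_id, r.chrom, int(r.start), int(r.end), r.strand, r.biotype)
        for r in df.itertuples(index=False)
    ]


def sample_name(time_hours: float, replicate: str | int) -> str:
    return f"T{time_hours:g}_R{replicate}"


class TimeCourseExperiment:
    """Gene x sample counts with sample times, plus normalized expression.

    Parameters
    ----------
    counts
        Non-negative integer counts, genes as rows, samples as columns.
    meta
        One row per sample (index = sample id) with columns ``time_hours``
        and ``replicate``.  (time, replicate) pairs must be unique.
    logexpr, cpm, norm_factors
        Populated by :func:`teb.expression.cpm_normalize`; absent on raw data.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        meta: pd.DataFrame,
        logexpr: pd.DataFrame | None = None,
        cpm: pd.DataFrame | None = None,
        norm_factors: pd.Series | None = None,
    ) -> None:
        if list(counts.columns) != list(meta.index):
            raise ValueError("counts columns must match meta index (sample ids)")
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        pairs = list(zip(meta["time_hours"], meta["replicate"]))
        if len(set(pairs)) != len(pairs):
            raise ValueError("(time_hours, replicate) pairs must be unique")
        if norm_factors is not None and (norm_factors <= 0).any():
            raise ValueError("norm_factors must be positive")
        self.counts = counts
        self.meta = meta
        self.logexpr = logexpr
        self.cpm = cpm
        self.norm_factors = norm_factors

    # ------------------------------------------------------------------ views
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Sorted unique sampling times in hours."""
        return np.sort(self.meta["time_hours"].unique())

    @property
    def replicates(self) -> list:
        return sorted(self.meta["replicate"].unique())

    def require_logexpr(self) -> pd.DataFrame:
        if self.logexpr is None:
            raise ValueError("experiment is not normalized; run cpm_normalize first")
        return self.logexpr

    # ------------------------------------------------------------- operations
    def subset_genes(self, gene_ids: Sequence[str]) -> "TimeCourseExperiment":
        keep = self.counts.index.intersection(gene_ids)
        return TimeCourseExperiment(
            self.counts.loc[keep],
            self.meta,
            None if self.logexpr is None else self.logexpr.loc[keep],
            None if self.cpm is None else self.cpm.loc[keep],
            self.norm_factors,
        )

    def replicate_mean(self, values: str = "logexpr") -> pd.DataFrame:
        """Per-gene profile averaged over replicates; columns = sorted times."""
        mat = {"logexpr": self.logexpr, "cpm": self.cpm, "counts": self.counts}[values]
        if mat is None:
            raise ValueError(f"{values} not available; normalize first")
        grouped = mat.T.groupby(self.meta["time_hours"]).mean().T
        return grouped[np.sort(grouped.columns)]

    def replicate_profile(self, replicate, values: str = "logexpr") -> pd.DataFrame:
        """Per-gene profile of a single replicate; columns = sorted times."""
        mat = {"logexpr": self.logexpr, "cpm": self.cpm, "counts": self.counts}[values]
        if mat is None:
            raise ValueError(f"{values} not available; normalize first")
        sel = self.meta.index[self.meta["replicate"] == replicate]
        sub = mat[sel]
        sub.columns = self.meta.loc[sel, "time_hours"].values
        return sub[np.sort(sub.columns)]
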