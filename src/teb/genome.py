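"""Genomic-layout analyses: bidirectional promoter pairs, co-expression regions.

Bidirectional pairs are two expressed genes on opposite strands transcribed
head-to-head (divergently) with transcriptional start sites strictly less
than 2,000 bp apart; multi-candidate conflicts are resolved by greedy
nearest-distance matching so each gene joins at most one pair.

Co-expression regions are maximal runs of >= 5 genes that are consecutive in
genomic order AMONG EXPRESSED GENES on a chromosome, where every adjacent
pair's replicate-mean temporal Pearson correlation exceeds 0.5.  Regions are
then tested for containment in single TADs and grouped into modules by
correlating their mean profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .experiment import TimeCourseExperiment
from .lag import best_lag_correlation


def _pair_biotype(b1: str, b2: str) -> str:
    c1 = "coding" if b1 == "protein_coding" else "noncoding"
    c2 = "coding" if b2 == "protein_coding" else "noncoding"
    return "-".join(sorted([c1, c2], reverse=True))  # coding-coding / coding-noncoding / ...


@dataclass
class BidirectionalPair:
    gene_a: str  # minus-strand member
    gene_b: str  # plus-strand member
    tss_distance_bp: int
    pair_biotype: str
    correlation: float | None = None
    driver: str = "none"  # "a", "b" or "none"
    driver_lag_hours: float | None = None


def candidate_bidirectional(genes: pd.DataFrame, max_dist_bp: int = 2000) -> list[tuple]:
    """All (minus gene, plus gene, distance) triples meeting the pair rule.

    Head-to-head: the minus-strand gene's TSS lies at or upstream (left) of
    the plus-strand gene's TSS, and the TSS distance is strictly below
    ``max_dist_bp``.
    """
    out = []
    for chrom, sub in genes.groupby("chrom", sort=True):
        minus = sub[sub["strand"] == "-"]
        plus = sub[sub["strand"] == "+"]
        for a in minus.itertuples(index=False):
            for b in plus.itertuples(index=False):
                d = b.tss - a.tss
                if 0 <= d < max_dist_bp:
                    out.append((a.gene_id, b.gene_id, int(d)))
    return out


def find_bidirectional_pairs(
    genes: pd.DataFrame, max_dist_bp: int = 2000
) -> list[BidirectionalPair]:
    """Greedy nearest-distance matching over all head-to-head candidates."""
    cands = candidate_bidirectional(genes, max_dist_bp)
    cands.sort(key=lambda c: (c[2], c[0], c[1]))
    used: set = set()
    pairs = []
    for a, b, d in cands:
        if a in used or b in used:
            continue
        used.update((a, b))
        pairs.append(
            BidirectionalPair(
                a, b, d, _pair_biotype(genes.loc[a, "biotype"], genes.loc[b, "biotype"])
            )
        )
    return pairs


def pair_statistics(
    pairs: list[BidirectionalPair],
    expt: TimeCourseExperiment,
    seed: int = 0,
    n_random: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-pair temporal correlation and expression difference vs random pairs."""
    if not pairs:
        raise ValueError("no pairs to evaluate")
    prof = expt.replicate_mean("logexpr")
    logexpr = expt.require_logexpr()
    med = logexpr.median(axis=1)
    rows = []
    for p in pairs:
        r = float(np.corrcoef(prof.loc[p.gene_a], prof.loc[p.gene_b])[0, 1])
        p.correlation = r
        rows.append(
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "tss_distance_bp": p.tss_distance_bp,
                "pair_biotype": p.pair_biotype,
                "r": r,
                "abs_delta_median_logexpr": abs(med[p.gene_a] - med[p.gene_b]),
            }
        )
    table = pd.DataFrame(rows)
    rng = np.random.default_rng(seed)
    n_rand = len(pairs) if n_random is None else n_random
    universe = np.asarray(expt.gene_ids)
    rand_r = []
    for _ in range(n_rand):
        a, b = rng.choice(universe, size=2, replace=False)
        rand_r.append(float(np.corrcoef(prof.loc[a], prof.loc[b])[0, 1]))
    summary = {
        "mean_pair_r": float(table["r"].mean()),
        "mean_random_r": float(np.mean(rand_r)),
        "n_pairs": len(pairs),
        "n_random": n_rand,
    }
    return table, summary


def assign_pair_driver(
    pair: BidirectionalPair,
    expt: TimeCourseExperiment,
    max_lag_samples: int = 3,
    r_threshold: float = 0.8,
) -> BidirectionalPair:
    """Which member's expression leads the other at peak correlation.

    Positive best lag of (a -> b) means gene a leads (driver a); negative
    means gene b leads.  Lag 0 or a peak correlation at or below the
    threshold yields no driver.
    """
    prof = expt.replicate_mean("logexpr")
    times = prof.columns.to_numpy(dtype=float)
    dt = float(np.diff(times).min())
    res = best_lag_correlation(
        prof.loc[pair.gene_a].to_numpy(),
        prof.loc[pair.gene_b].to_numpy(),
        max_lag_samples,
        dt_hours=dt,
    )
    if not res.defined or res.max_r <= r_threshold or res.best_lag == 0:
        pair.driver = "none"
        pair.driver_lag_hours = None if not res.defined else res.best_lag_hours
        return pair
    pair.driver = "a" if res.best_lag > 0 else "b"
    pair.driver_lag_hours = abs(res.best_lag_hours)
    return pair


# ------------------------------------------------------------------- regions
@dataclass
class CoexpressionRegion:
    chrom: str
    start: int  # TSS of first member gene
    end: int  # gene end of last member gene
    gene_ids: list
    mean_profile: pd.Series = field(repr=False, default=None)
    module_id: int | None = None

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def adjacent_correlations(
    ordered_genes: list, prof: pd.DataFrame
) -> np.ndarray:
    """Pearson r between each gene's profile and its next neighbor's."""
    mat = prof.loc[ordered_genes].to_numpy(dtype=float)
    out = np.empty(len(ordered_genes) - 1)
    for i in range(len(out)):
        a, b = mat[i], mat[i + 1]
        if a.std() == 0 or b.std() == 0:
            out[i] = np.nan
        else:
            out[i] = np.corrcoef(a, b)[0, 1]
    return out


def scan_coexpression_regions(
    genes: pd.DataFrame,
    expt: TimeCourseExperiment,
    min_genes: int = 5,
    r_min: float = 0.5,
) -> list[CoexpressionRegion]:
    """Linear scan for maximal co-expressed runs along each chromosome.

    ``genes`` should already be restricted to expressed genes; per chromosome
    they are ordered by TSS and maximal runs where every adjacent pair has
    r > ``r_min`` are emitted if they contain >= ``min_genes`` genes.
    """
    prof = expt.replicate_mean("logexpr")
    regions = []
    for chrom, sub in genes.groupby("chrom", sort=True):
        sub = sub[sub["gene_id"].isin(prof.index)]
        if len(sub) < min_genes:
            continue
        ordered = sub.reset_index(drop=True).sort_values(["tss", "gene_id"], kind="stable")
        ids = ordered["gene_id"].tolist()
        adj = adjacent_correlations(ids, prof)
        linked = np.nan_to_num(adj, nan=-np.inf) > r_min
        i = 0
        while i < len(ids):
            j = i
            while j < len(adj) and linked[j]:
                j += 1
            run = ids[i : j + 1]
            if len(run) >= min_genes:
                members = ordered[ordered["gene_id"].isin(run)]
                centered = prof.loc[run].sub(prof.loc[run].mean(axis=1), axis=0)
                regions.append(
                    CoexpressionRegion(
                        chrom,
                        int(members.iloc[0]["tss"]),
                        int(members["end"].max()),
                        run,
                        centered.mean(axis=0),
                    )
                )
            i = j + 1
    return regions


# ----------------------------------------------------------------------- TADs
def tad_containment(
    regions: list[CoexpressionRegion], tads: pd.DataFrame
) -> pd.DataFrame:
    """Classify each region as contained / spans-boundary / no-overlap.

    ``contained`` means the region interval is a subset of a single TAD
    interval (both 0-based half-open).  A gross chromosome-naming mismatch
    (no region chromosome present in the TAD set at all) raises an error
    listing the offending names.
    """
    if not regions:
        return pd.DataFrame(columns=["chrom", "start", "end", "status"])
    region_chroms = {r.chrom for r in regions}
    tad_chroms = set(tads["chrom"].unique())
    if len(tads) and not region_chroms & tad_chroms:
        raise ValueError(
            f"chromosome naming mismatch: regions use {sorted(region_chroms)}, "
            f"TADs use {sorted(tad_chroms)}"
        )
    trees = {
        chrom: IntervalTree.from_tuples(
            (row.start, row.end) for row in sub.itertuples(index=False)
        )
        for chrom, sub in tads.groupby("chrom")
    }
    rows = []
    for reg in regions:
        tree = trees.get(reg.chrom)
        hits = tree.overlap(reg.start, reg.end) if tree is not None else set()
        if not hits:
            status = "no-overlap"
        elif any(iv.begin <= reg.start and reg.end <= iv.end for iv in hits):
            status = "contained"
        else:
            status = "spans-boundary"
        rows.append({"chrom": reg.chrom, "start": reg.start, "end": reg.end, "status": status})
    return pd.DataFrame(rows)


# -------------------------------------------------------------------- modules
def group_region_modules(
    regions: list[CoexpressionRegion], r_module: float = 0.5
) -> pd.DataFrame:
    """Connected components of regions whose mean profiles correlate > r_module.

    Each module gets a trend label from the sign of the end-minus-start
    change of its member-average profile.
    """
    if not regions:
        return pd.DataFrame(columns=["region_index", "module_id", "trend"])
    g = nx.Graph()
    g.add_nodes_from(range(len(regions)))
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            r = np.corrcoef(regions[i].mean_profile, regions[j].mean_profile)[0, 1]
            if r > r_module:
                g.add_edge(i, j)
    rows = []
    components = sorted(nx.connected_components(g), key=min)
    for mod_id, comp in enumerate(components):
        profs = [regions[i].mean_profile for i in sorted(comp)]
        mean_prof = pd.concat(profs, axis=1).mean(axis=1)
        trend = "increasing" if mean_prof.iloc[-1] - mean_prof.iloc[0] >= 0 else "decreasing"
        for i in sorted(comp):
            regions[i].module_id = mod_id
            rows.append({"region_index": i, "module_id": mod_id, "trend": trend})
    return pd.DataFrame(rows)


def regions_to_frame(regions: list[CoexpressionRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "region_id": [f"region_{i}" for i in range(len(regions))],
            "n_genes": [r.n_genes for r in regions],
            "module_id": [r.module_id for r in regions],
            "gene_ids": [",".join(r.gene_ids) for r in regions],
        }
    )
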