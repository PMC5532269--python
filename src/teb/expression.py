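"""Normalization, expression filtering, smoothing deviation, PCA, clustering.

The shared substrate for the downstream stages: counts are library-size
normalized to CPM and transformed as log2(CPM + 0.5); the dynamic-gene screen
keeps genes above 1 CPM in at least two libraries; sub-daily deviation is
scored against a 24 h loess smooth of the replicate-mean profile.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from statsmodels.nonparametric.smoothers_lowess import lowess

from .experiment import TimeCourseExperiment

log = logging.getLogger(__name__)


class NormalizationError(ValueError):
    pass


def cpm_normalize(expt: TimeCourseExperiment) -> TimeCourseExperiment:
    """Counts-per-million normalization with log2(CPM + 0.5) transform.

    Raises :class:`NormalizationError` naming any sample with zero total
    counts.  The per-sample library sizes (in millions) are recorded as
    ``norm_factors``.  Re-normalizing an already normalized experiment is a
    no-op: everything is recomputed from the raw counts.
    """
    libsize = expt.counts.sum(axis=0).astype(float)
    zero = libsize.index[libsize == 0].tolist()
    if zero:
        raise NormalizationError(f"samples with zero library size: {zero}")
    cpm = expt.counts.div(libsize, axis=1) * 1e6
    logexpr = np.log2(cpm + 0.5)
    return TimeCourseExperiment(
        expt.counts, expt.meta, logexpr=logexpr, cpm=cpm, norm_factors=libsize / 1e6
    )


def filter_expressed(
    expt: TimeCourseExperiment, min_cpm: float = 1.0, min_samples: int = 2
) -> TimeCourseExperiment:
    """Keep genes with CPM strictly above ``min_cpm`` in >= ``min_samples`` samples."""
    if expt.cpm is None:
        raise ValueError("CPM not computed; run cpm_normalize first")
    keep = (expt.cpm > min_cpm).sum(axis=1) >= min_samples
    n_in, n_out = len(keep), int(keep.sum())
    log.info("filter_expressed: %d of %d genes retained (>%g CPM in >=%d samples)",
             n_out, n_in, min_cpm, min_samples)
    if n_out == 0:
        log.warning("filter_expressed removed every gene")
    return expt.subset_genes(expt.gene_ids[keep])


def loess_deviation(
    expt: TimeCourseExperiment, span_hours: float = 24.0, top_frac: float = 0.05
) -> pd.DataFrame:
    """Score each gene's deviation from its 24 h loess-smoothed profile.

    A local linear smoother with tricube weights (bandwidth ``span_hours``)
    is fit to the replicate-mean log2 profile; the deviation score is the
    root-mean-square residual.  Genes in the top ``top_frac`` by deviation
    are flagged as showing sub-daily structure.
    """
    prof = expt.replicate_mean("logexpr")
    times = prof.columns.to_numpy(dtype=float)
    if times.size < 5:
        raise ValueError("need at least 5 time points to smooth")
    dt = np.diff(np.sort(times)).min()
    if span_hours < 2 * dt:
        raise ValueError(f"span_hours={span_hours} shorter than 2 sampling intervals")
    frac = min(1.0, span_hours / (times.max() - times.min()))
    dev = np.empty(prof.shape[0])
    vals = prof.to_numpy()
    for i in range(vals.shape[0]):
        # it=0: plain tricube local-linear fit.  Robustness iterations would
        # treat exactly the sub-daily excursions we are scoring as outliers.
        smooth = lowess(vals[i], times, frac=frac, it=0, return_sorted=False)
        dev[i] = math.sqrt(np.mean((vals[i] - smooth) ** 2))
    out = pd.DataFrame({"gene_id": prof.index, "deviation": dev}).set_index(
        "gene_id", drop=False
    )
    n_flag = math.ceil(top_frac * len(out))
    ranked = out["deviation"].rank(method="first", ascending=False)
    out["flagged"] = ranked <= n_flag
    return out


def variable_gene_pca(
    expt: TimeCourseExperiment, n_top: int = 2000, n_pc: int = 3, n_loading: int = 500
):
    """PCA of samples on the ``n_top`` most variable genes (log2 scale).

    Returns (scores, loadings, eigenvalues, top_genes) where ``scores`` is a
    samples x n_pc frame, ``loadings`` genes x n_pc, and ``top_genes`` maps
    each component to its ``n_loading`` highest-|loading| genes.
    """
    logexpr = expt.require_logexpr()
    if n_top > expt.n_genes:
        raise ValueError(f"n_top={n_top} exceeds {expt.n_genes} genes")
    variances = logexpr.var(axis=1, ddof=1)
    top = variances.sort_values(ascending=False, kind="stable").index[:n_top]
    X = logexpr.loc[top].T.to_numpy(dtype=float)  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    if not np.any(X):
        raise ValueError("expression matrix is constant; PCA undefined")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each PC is positive
    for k in range(min(n_pc, S.size)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    n_pc = min(n_pc, S.size)
    scores = pd.DataFrame(
        U[:, :n_pc] * S[:n_pc], index=logexpr.columns, columns=[f"PC{k+1}" for k in range(n_pc)]
    )
    loadings = pd.DataFrame(
        Vt[:n_pc].T, index=top, columns=[f"PC{k+1}" for k in range(n_pc)]
    )
    eigenvalues = (S**2) / (X.shape[0] - 1)
    top_genes = {
        f"PC{k+1}": loadings[f"PC{k+1}"].abs().sort_values(ascending=False, kind="stable")
        .index[:n_loading].tolist()
        for k in range(n_pc)
    }
    return scores, loadings, eigenvalues, top_genes


def cluster_profiles(profiles: pd.DataFrame, k: int, seed: int, n_init: int = 25):
    """K-means on per-gene standardized time profiles.

    ``profiles`` is genes x time points.  Profiles are z-scored per gene
    (constant profiles fall at the origin).  Returns (labels Series,
    centroids DataFrame k x time).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > profiles.shape[0]:
        raise ValueError(f"k={k} exceeds {profiles.shape[0]} profiles")
    X = profiles.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(Z)
    centroids = pd.DataFrame(km.cluster_centers_, columns=profiles.columns)
    return pd.Series(labels, index=profiles.index, name="cluster"), centroids
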