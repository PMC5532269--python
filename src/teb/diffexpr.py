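"""Moderated differential expression between time points and the slRNA screen.

Each gene is fit as a one-way layout over time points on log2(CPM + 0.5)
values.  Per-gene residual variances are shrunk by empirical Bayes: the
marginal distribution of the sample variances is a scaled F, and its
hyperparameters (prior df ``d0``, prior variance ``s0^2``) are estimated in
closed form from the moments of log s^2.  The moderated t-statistic

    t_g = (mean_b - mean_a) / sqrt(s2_post_g * (1/n_a + 1/n_b)),
    s2_post_g = (d0 * s0^2 + d * s2_g) / (d0 + d),

has d0 + d degrees of freedom.

The slRNA (short-lived RNA) screen calls genes that change significantly
within a 24 h window (w vs w+6, w+12, w+18) while showing no significant
change between any pair of 24-hourly time points.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .experiment import TimeCourseExperiment


class DesignError(ValueError):
    pass


class DependencyError(ValueError):
    pass


# ------------------------------------------------------------------ model fit
@dataclass
class GeneModelFit:
    """Per-gene group means and pooled residual variance of a one-way layout."""

    means: pd.DataFrame  # genes x time points
    s2: pd.Series  # pooled residual variance per gene
    df_residual: int
    n_per_group: dict  # time -> replicate count


def fit_gene_models(expt: TimeCourseExperiment) -> GeneModelFit:
    logexpr = expt.require_logexpr()
    times = expt.meta["time_hours"]
    groups = {t: expt.meta.index[times == t] for t in np.sort(times.unique())}
    n_per_group = {t: len(ix) for t, ix in groups.items()}
    if any(n < 1 for n in n_per_group.values()):
        raise DesignError("every time point needs at least one sample")
    d = logexpr.shape[1] - len(groups)
    if d < 1:
        raise DesignError("no residual degrees of freedom; need replicates")
    means = pd.DataFrame(index=logexpr.index)
    rss = np.zeros(logexpr.shape[0])
    for t, ix in groups.items():
        sub = logexpr[ix].to_numpy()
        m = sub.mean(axis=1)
        means[t] = m
        rss += ((sub - m[:, None]) ** 2).sum(axis=1)
    return GeneModelFit(means, pd.Series(rss / d, index=logexpr.index), d, n_per_group)


# ----------------------------------------------------------- variance shrinkage
def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


@dataclass
class ModeratedVariances:
    d0: float  # prior degrees of freedom (inf => complete pooling)
    s0_2: float  # prior variance
    s2_post: pd.Series  # posterior (shrunk) variances


def moderate_variances(s2: pd.Series, d: int) -> ModeratedVariances:
    """Closed-form method-of-moments empirical Bayes on log sample variances.

    With s2_g ~ s0^2 * F(d, d0) marginally, log s2 has mean
    log s0^2 + [psi(d/2) - log(d/2)] - [psi(d0/2) - log(d0/2)] and variance
    psi'(d/2) + psi'(d0/2).  When the observed variance of log s2 does not
    exceed psi'(d/2) there is no evidence of gene-to-gene variance spread and
    d0 = inf is returned (posterior variance = s0^2 for every gene).
    """
    ok = s2[np.isfinite(s2) & (s2 > 0)]
    if len(ok) < 10:
        raise ValueError("need >= 10 genes with positive finite variances")
    z = np.log(ok.to_numpy())
    e_z = z.mean()
    var_z = z.var(ddof=1)
    excess = var_z - special.polygamma(1, d / 2.0)
    mean_adjust = special.digamma(d / 2.0) - np.log(d / 2.0)
    if excess <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(e_z - mean_adjust))
        post = pd.Series(np.full(len(s2), s0_2), index=s2.index)
        return ModeratedVariances(d0, s0_2, post)
    d0 = 2.0 * trigamma_inverse(float(excess))
    s0_2 = float(
        np.exp(e_z - mean_adjust + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    )
    post = (d0 * s0_2 + d * s2) / (d0 + d)
    return ModeratedVariances(float(d0), s0_2, post)


# ----------------------------------------------------------------- inference
def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class Contrast:
    time_a: float
    time_b: float

    def __post_init__(self) -> None:
        if self.time_a == self.time_b:
            raise ValueError("contrast requires two distinct time points")

    @property
    def label(self) -> str:
        return f"t{self.time_a:g}_vs_t{self.time_b:g}"


@dataclass
class DEResultSet:
    """Per-(gene, contrast) moderated statistics plus EB hyperparameters."""

    table: pd.DataFrame  # gene, contrast, time_a, time_b, lfc, t, p, padj
    d0: float
    s0_2: float
    df_residual: int


def moderated_t_table(
    fit: GeneModelFit, mod: ModeratedVariances, contrasts: list[Contrast]
) -> pd.DataFrame:
    df_total = mod.d0 + fit.df_residual
    rows = []
    s2p = mod.s2_post.to_numpy()
    for c in contrasts:
        if c.time_a not in fit.n_per_group or c.time_b not in fit.n_per_group:
            raise DesignError(f"contrast {c.label} references unknown time point")
        na, nb = fit.n_per_group[c.time_a], fit.n_per_group[c.time_b]
        lfc = (fit.means[c.time_b] - fit.means[c.time_a]).to_numpy()
        se = np.sqrt(s2p * (1.0 / na + 1.0 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, lfc / se, np.where(lfc == 0, 0.0, np.inf * np.sign(lfc)))
        p = 2.0 * stats.t.sf(np.abs(tstat), df=df_total)
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": fit.means.index,
                    "contrast": c.label,
                    "time_a": c.time_a,
                    "time_b": c.time_b,
                    "lfc": lfc,
                    "t": tstat,
                    "p": p,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def window_contrasts(times) -> tuple[list[Contrast], list[Contrast]]:
    """Intra-window and 24-hourly contrasts for the slRNA screen.

    For each 24 h window start w, the intra contrasts are w vs w+6, w+12,
    w+18; the daily contrasts are all pairs of 24-hourly time points.
    """
    times = np.sort(np.asarray(times, dtype=float))
    daily_times = [t for t in times if t % 24 == 0]
    intra = []
    for w in daily_times:
        for off in (6.0, 12.0, 18.0):
            if w + off in times:
                intra.append(Contrast(w, w + off))
    daily = [Contrast(a, b) for a, b in itertools.combinations(daily_times, 2)]
    return intra, daily


def run_de(expt: TimeCourseExperiment, contrasts: list[Contrast] | None = None) -> DEResultSet:
    """Fit, moderate, test the given contrasts (default: the slRNA contrast set).

    BH adjustment is applied across genes within each contrast.
    """
    fit = fit_gene_models(expt)
    mod = moderate_variances(fit.s2, fit.df_residual)
    if contrasts is None:
        intra, daily = window_contrasts(expt.times)
        contrasts = intra + daily
    table = moderated_t_table(fit, mod, contrasts)
    table["padj"] = (
        table.groupby("contrast", group_keys=False)["p"].transform(lambda p: bh_adjust(p))
    )
    return DEResultSet(table, mod.d0, mod.s0_2, fit.df_residual)


# -------------------------------------------------------------- slRNA screen
def classify_slrna(de: DEResultSet, alpha: float = 1e-4) -> pd.DataFrame:
    """Call short-lived RNAs from the window/daily contrast grid.

    A gene is an slRNA if at least one intra-window contrast is significant
    (adjusted p < ``alpha``) while no 24-hourly pairwise contrast is; it is
    sustained if some window has >= 2 of its 3 intra contrasts significant
    (significant for more than half of the measurable sub-daily offsets).
    """
    tab = de.table
    is_daily = (tab["time_a"] % 24 == 0) & (tab["time_b"] % 24 == 0)
    is_intra = (tab["time_a"] % 24 == 0) & ((tab["time_b"] - tab["time_a"]).isin([6.0, 12.0, 18.0]))
    windows = sorted(tab.loc[is_intra, "time_a"].unique())
    if not windows:
        raise DependencyError("no intra-window contrasts present in DE results")
    n_daily_times = len(
        set(tab.loc[is_daily, "time_a"]).union(tab.loc[is_daily, "time_b"])
    )
    expected_daily = n_daily_times * (n_daily_times - 1) // 2
    if tab.loc[is_daily, "contrast"].nunique() != expected_daily:
        raise DependencyError("incomplete 24-hourly pairwise contrast grid")

    sig = tab["padj"] < alpha
    daily_hits = tab[is_daily & sig].groupby("gene_id").size()
    genes = tab["gene_id"].unique()
    any_daily = pd.Series(genes, index=genes).isin(daily_hits.index)

    intra_tab = tab[is_intra]
    hit_counts = (
        intra_tab.assign(sig=sig[is_intra].values)
        .groupby(["gene_id", "time_a"])["sig"]
        .sum()
        .unstack(fill_value=0)
        .reindex(genes, fill_value=0)
    )
    best_window = hit_counts.idxmax(axis=1)
    max_hits = hit_counts.max(axis=1)
    rows = pd.DataFrame(
        {
            "gene_id": genes,
            "window_start": np.where(max_hits > 0, best_window, np.nan),
            "intra_window_hits": max_hits.astype(int),
            "any_daily_hit": any_daily.values,
        }
    )
    rows["is_slrna"] = (rows["intra_window_hits"] >= 1) & (~rows["any_daily_hit"])
    rows["is_sustained"] = rows["is_slrna"] & (rows["intra_window_hits"] >= 2)
    return rows.set_index("gene_id", drop=False)
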