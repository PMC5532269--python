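"""Lagged cross-correlation machinery for regulator -> target inference.

The core primitive slides one series against another over integer sample
lags and reports the lag maximizing (or minimizing) the Pearson correlation
of the overlapping segments — no padding, no wrap-around.  Sign convention:
a POSITIVE lag means the source (TF or lncRNA) leads the target.

On top of it sit: TF->target delay histograms with a 500-draw random-set
null envelope (per-lag 95% quantiles), TF activity profiles (median fold
change of the target group relative to time 0), and lncRNA target inference
on 100-point interpolated profiles with the lag window restricted to
[0, 18 h] so only lncRNA-led relationships are counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .experiment import LNCRNA_BIOTYPES, TimeCourseExperiment
from .periodicity import interpolate_series


@dataclass
class LagResult:
    source_gene: str | None
    target_gene: str | None
    best_lag: int | None  # in samples of whatever grid was used
    best_lag_hours: float | None
    max_r: float | None
    passed: bool = False

    @property
    def defined(self) -> bool:
        return self.best_lag is not None


def _pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def best_lag_correlation(
    x: np.ndarray,
    y: np.ndarray,
    max_lag_samples: int,
    mode: str = "positive",
    min_lag_samples: int | None = None,
    dt_hours: float = 1.0,
) -> LagResult:
    """Best integer-lag Pearson correlation between two equal-length series.

    For lag l >= 0 the correlation is between x[0:N-l] and y[l:N] (the source
    x leading); negative lags mirror this.  ``mode="positive"`` maximizes r,
    ``mode="negative"`` minimizes it.  Ties are broken toward the smallest
    |l| and then toward positive l.  Lags whose overlap has zero variance are
    skipped; if every lag is skipped the result is the undefined sentinel.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    n = x.size
    if n <= max_lag_samples + 3:
        raise ValueError("series too short for the requested maximum lag")
    lo = -max_lag_samples if min_lag_samples is None else min_lag_samples
    hi = max_lag_samples
    # tie-break ordering: 0, +1, -1, +2, -2, ... restricted to [lo, hi]
    ordered = sorted(range(lo, hi + 1), key=lambda l: (abs(l), l < 0))
    best_lag, best_r = None, None
    for l in ordered:
        if l >= 0:
            a, b = x[: n - l], y[l:]
        else:
            a, b = x[-l:], y[: n + l]
        r = _pearson(a, b)
        if r is None:
            continue
        better = (
            best_r is None
            or (mode == "positive" and r > best_r)
            or (mode == "negative" and r < best_r)
        )
        if better:
            best_lag, best_r = l, r
    if best_lag is None:
        return LagResult(None, None, None, None, None)
    return LagResult(None, None, best_lag, best_lag * dt_hours, best_r)


def _ordered_lags(lo: int, hi: int) -> list[int]:
    """Tie-break order: 0, +1, -1, +2, -2, ... restricted to [lo, hi]."""
    return sorted(range(lo, hi + 1), key=lambda l: (abs(l), l < 0))


def lag_correlation_matrix(x: np.ndarray, Y: np.ndarray, lags) -> np.ndarray:
    """Pearson r of ``x`` against every row of ``Y`` at each integer lag.

    Same overlap convention as :func:`best_lag_correlation`; entry [i, j] is
    the correlation at ``lags[i]`` for series ``Y[j]`` (NaN where either
    overlap segment has zero variance).
    """
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = x.size
    out = np.empty((len(lags), Y.shape[0]))
    for i, l in enumerate(lags):
        if l >= 0:
            a, B = x[: n - l], Y[:, l:]
        else:
            a, B = x[-l:], Y[:, : n + l]
        ac = a - a.mean()
        Bc = B - B.mean(axis=1, keepdims=True)
        denom = np.sqrt((ac @ ac) * (Bc * Bc).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Bc @ ac) / denom
        r[denom == 0] = np.nan
        out[i] = r
    return out


def _best_lags(R: np.ndarray, lags, mode: str = "positive"):
    """Tie-break-consistent best lag per column of a lag x series r-matrix."""
    # iterate lags in the canonical order, keeping the first strict optimum
    idx = sorted(range(len(lags)), key=lambda i: (abs(lags[i]), lags[i] < 0))
    m = R.shape[1]
    best_r = np.full(m, np.nan)
    best_lag = np.full(m, np.iinfo(np.int64).min, dtype=np.int64)
    for i in idx:
        r = R[i]
        fresh = np.isnan(best_r) & ~np.isnan(r)
        if mode == "positive":
            better = fresh | (~np.isnan(r) & (r > best_r))
        else:
            better = fresh | (~np.isnan(r) & (r < best_r))
        best_r[better] = r[better]
        best_lag[better] = lags[i]
    defined = ~np.isnan(best_r)
    return best_lag, best_r, defined


# ------------------------------------------------------------ TF target delays
def tf_target_delays(
    tf: str,
    targets,
    expt: TimeCourseExperiment,
    r_threshold: float = 0.8,
    max_lag_samples: int = 3,
) -> tuple[pd.Series, list[LagResult]]:
    """Best lag of each target against the TF's replicate-mean profile.

    Returns (histogram of best lags in hours over PASSING targets,
    per-target LagResult list).  ``passed`` means max r > r_threshold.
    """
    targets = list(targets)
    if not targets:
        raise ValueError("empty target set")
    prof = expt.replicate_mean("logexpr")
    times = prof.columns.to_numpy(dtype=float)
    dt = float(np.diff(times).min())
    src = prof.loc[tf].to_numpy()
    lags = list(range(-max_lag_samples, max_lag_samples + 1))
    R = lag_correlation_matrix(src, prof.loc[targets].to_numpy(), lags)
    best_lag, best_r, defined = _best_lags(R, lags)
    results = []
    for j, tgt in enumerate(targets):
        if defined[j]:
            res = LagResult(tf, tgt, int(best_lag[j]), best_lag[j] * dt, float(best_r[j]))
            res.passed = res.max_r > r_threshold
        else:
            res = LagResult(tf, tgt, None, None, None)
        results.append(res)
    lags_h = [r.best_lag_hours for r in results if r.passed]
    bins = np.arange(-max_lag_samples, max_lag_samples + 1) * dt
    hist = pd.Series(0, index=bins, dtype=int)
    for lh in lags_h:
        hist[lh] += 1
    return hist, results


@dataclass
class DelayNull:
    """Per-lag 95% quantile envelope of passing-target counts from random sets."""

    quantiles: pd.Series  # index = lag hours
    n_draws: int
    set_size: int
    level: float = 0.95


def delay_null_envelope(
    expt: TimeCourseExperiment,
    tf: str,
    set_size: int,
    n_draws: int = 500,
    seed: int = 0,
    r_threshold: float = 0.8,
    max_lag_samples: int = 3,
) -> DelayNull:
    """Null delay histograms from ``n_draws`` random same-size gene sets."""
    universe = [g for g in expt.gene_ids if g != tf]
    if len(universe) < 10 * set_size:
        raise ValueError(
            f"gene universe ({len(universe)}) must be >= 10 x set size ({set_size})"
        )
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_draws):
        sel = rng.choice(universe, size=set_size, replace=False)
        hist, _ = tf_target_delays(tf, sel, expt, r_threshold, max_lag_samples)
        draws.append(hist)
    mat = pd.concat(draws, axis=1)
    q = mat.quantile(0.95, axis=1)
    return DelayNull(q, n_draws, set_size)


def tf_activity_profile(targets, expt: TimeCourseExperiment) -> pd.Series:
    """Median log2 fold change (relative to time 0) over the target group.

    Replicates are averaged first; by construction the value at t = 0 is 0.
    """
    targets = list(targets)
    if not targets:
        raise ValueError("empty target set")
    prof = expt.replicate_mean("logexpr").loc[targets]
    if 0.0 not in prof.columns:
        raise ValueError("time 0 missing from the design")
    fc = prof.sub(prof[0.0], axis=0)
    return fc.median(axis=0)


# --------------------------------------------------------------- lncRNA targets
def select_candidate_lncrnas(
    expt: TimeCourseExperiment, annotation: pd.DataFrame, n: int = 50
) -> list:
    """Top ``n`` lncRNAs by a combined high-expression / high-variability rank.

    Genes are ranked separately by median log2 expression and by variance
    (descending); the union of the two top-n lists is ordered by the sum of
    the two ranks and truncated to n.
    """
    lnc = [
        g
        for g in expt.gene_ids
        if g in annotation.index and annotation.loc[g, "biotype"] in LNCRNA_BIOTYPES
    ]
    if not lnc:
        return []
    logexpr = expt.require_logexpr().loc[lnc]
    med = logexpr.median(axis=1).rank(ascending=False, method="first")
    var = logexpr.var(axis=1).rank(ascending=False, method="first")
    pool = set(med.index[med <= n]) | set(var.index[var <= n])
    combined = (med + var).loc[sorted(pool)]
    ordered = combined.sort_values(kind="stable").index.tolist()
    return ordered[:n]


def lncrna_target_inference(
    lncrnas,
    candidates,
    expt: TimeCourseExperiment,
    max_delay_hours: float = 18.0,
    r_threshold: float = 0.9,
    n_interp: int = 100,
) -> pd.DataFrame:
    """Lagged-correlation targets of each lncRNA, lncRNA strictly leading.

    Replicate-mean profiles are interpolated to ``n_interp`` points; lags are
    restricted to [0, max_delay_hours].  Candidates whose maximum correlation
    exceeds +r_threshold are positive targets; those dropping below
    -r_threshold are negative targets.
    """
    prof = expt.replicate_mean("logexpr")
    times = prof.columns.to_numpy(dtype=float)
    span = times[-1] - times[0]
    if max_delay_hours > span / 2:
        raise ValueError("max_delay_hours exceeds half the series span")
    grid = np.linspace(times[0], times[-1], n_interp)
    dt = grid[1] - grid[0]
    max_lag = int(np.floor(max_delay_hours / dt))
    lncrnas = list(lncrnas)
    candidates = list(candidates)
    dense = {
        g: interpolate_series(times, prof.loc[g].to_numpy(), n_interp)[1]
        for g in set(lncrnas) | set(candidates)
    }
    Y = np.vstack([dense[c] for c in candidates])
    lags = list(range(0, max_lag + 1))
    rows = []
    for lnc in lncrnas:
        R = lag_correlation_matrix(dense[lnc], Y, lags)
        pos_lag, pos_r, pos_def = _best_lags(R, lags, "positive")
        neg_lag, neg_r, neg_def = _best_lags(R, lags, "negative")
        for j, cand in enumerate(candidates):
            if cand == lnc:
                continue
            if pos_def[j] and pos_r[j] > r_threshold:
                rows.append((lnc, cand, "positive", pos_lag[j] * dt, float(pos_r[j])))
            if neg_def[j] and neg_r[j] < -r_threshold:
                rows.append((lnc, cand, "negative", neg_lag[j] * dt, float(neg_r[j])))
    return pd.DataFrame(
        rows, columns=["lncrna", "target", "association", "delay_hours", "r"]
    )
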