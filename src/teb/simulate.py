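"""Synthetic time-course generator with planted, recoverable signals.

Emulates the study design used throughout the package: a 21-point, 6-hourly
(0-120 h) bulk RNA-seq time course of differentiating embryoid bodies in
biological duplicate.  Counts are drawn negative-binomially around per-gene
mean CPM profiles assembled from planted log2-scale effects:

* ``pulse``     — raised-cosine bump inside a sub-24 h window (slRNA class);
                  expression returns exactly to baseline at the window edges,
                  so 24-hourly samples see no change.
* ``sinusoid``  — cosine with a given period/amplitude/phase (cycRNA class
                  when the period is below 36 h).
* ``trend``     — logistic rise or fall across the course.
* ``lagged_target`` — a regulator's effect re-evaluated at ``t - lag`` and
                  optionally sign-flipped.
* ``bidirectional_pair`` — two genes placed head-to-head at an exact TSS
                  distance sharing a profile (optionally lagged/sign-flipped).
* ``coexpression_block`` — a run of consecutively placed genes sharing a
                  smooth random profile.

Every planted signal is registered in a :class:`TruthTable` so downstream
callers can be scored for recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .experiment import GeneModel, TimeCourseExperiment, genes_to_frame, sample_name

SIGNAL_KINDS = frozenset(
    {
        "baseline",
        "trend",
        "pulse",
        "sinusoid",
        "lagged_target",
        "bidirectional_pair",
        "coexpression_block",
    }
)


class PlacementError(ValueError):
    """Requested gene layout does not fit on the configured chromosomes."""


@dataclass(frozen=True)
class PlantedSignal:
    """One planted effect applied to one or more genes.

    ``params`` are kind-specific (hours for times/periods/lags, log2 units for
    amplitudes, bp for distances).  See the module docstring for the shapes.
    """

    kind: str
    gene_ids: tuple
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in SIGNAL_KINDS:
            raise ValueError(f"unknown signal kind {self.kind!r}")
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        p = self.params
        if self.kind == "pulse":
            if p["duration_h"] <= 0:
                raise ValueError("pulse duration must be positive")
            if p["amplitude"] < 0:
                raise ValueError("pulse amplitude must be non-negative")
        if self.kind == "sinusoid":
            if p["period_h"] <= 0:
                raise ValueError("sinusoid period must be positive")
            if p["amplitude"] < 0:
                raise ValueError("sinusoid amplitude must be non-negative")
        if self.kind == "bidirectional_pair":
            if len(self.gene_ids) != 2:
                raise ValueError("bidirectional_pair needs exactly two genes")
            if p["distance_bp"] < 0:
                raise ValueError("TSS distance must be non-negative")
        if self.kind == "coexpression_block" and len(self.gene_ids) < 2:
            raise ValueError("coexpression_block needs at least two genes")


@dataclass
class SimConfig:
    """Study-design parameters plus the list of planted signals.

    Defaults reproduce the emulated design: 21 time points 6 h apart
    (0-120 h) in biological duplicate.  ``noise_sd`` is the per-replicate
    biological noise on the log2 scale; ``nb_dispersion`` is the
    negative-binomial overdispersion (variance = m + phi * m^2).
    """

    n_genes: int
    n_timepoints: int = 21
    dt_hours: float = 6.0
    n_replicates: int = 2
    library_size_mean: float = 5e6
    library_size_cv: float = 0.10
    nb_dispersion: float = 0.005
    noise_sd: float = 0.2
    baseline_log2_cpm: float = 6.0
    baseline_sd: float = 1.0
    seed: int = 0
    planted: list = field(default_factory=list)
    # layout of the synthetic genome
    n_chroms: int = 3
    gene_length_bp: int = 2000
    gene_spacing_bp: int = 10000
    chrom_lengths: dict | None = None
    filler_lncrna_frac: float = 0.10

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_timepoints <= 0 or self.n_replicates <= 0:
            raise ValueError("n_genes, n_timepoints, n_replicates must be positive")
        if self.dt_hours <= 0 or self.library_size_mean <= 0:
            raise ValueError("dt_hours and library_size_mean must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        n_planted = sum(len(s.gene_ids) for s in self.planted)
        if n_planted > self.n_genes:
            raise ValueError(f"{n_planted} planted genes exceed n_genes={self.n_genes}")
        seen: set = set()
        for sig in self.planted:
            dup = seen.intersection(sig.gene_ids)
            if dup and sig.kind not in {"lagged_target"}:
                raise ValueError(f"genes planted twice: {sorted(dup)[:5]}")
            seen.update(sig.gene_ids)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.dt_hours

    @property
    def span_hours(self) -> float:
        return (self.n_timepoints - 1) * self.dt_hours


class TruthTable:
    """Registry of planted signals, one row per (gene, signal kind)."""

    COLUMNS = ["gene_id", "kind", "params"]

    def __init__(self, df: pd.DataFrame) -> None:
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_signals(cls, signals: Iterable[PlantedSignal]) -> "TruthTable":
        rows = []
        for sig in signals:
            for i, g in enumerate(sig.gene_ids):
                params = dict(sig.params)
                params["member_index"] = i
                if len(sig.gene_ids) > 1:
                    params["signal_genes"] = list(sig.gene_ids)
                rows.append((g, sig.kind, json.dumps(params, sort_keys=True)))
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS))

    def genes_of(self, kind: str) -> list:
        return self.df.loc[self.df["kind"] == kind, "gene_id"].tolist()

    def params_of(self, gene_id: str, kind: str) -> dict:
        sub = self.df[(self.df["gene_id"] == gene_id) & (self.df["kind"] == kind)]
        if sub.empty:
            raise KeyError(f"{gene_id} has no planted {kind}")
        return json.loads(sub.iloc[0]["params"])

    # ----------------------------------------------------- class truth sets
    def slrna_truth(self) -> set:
        """Genes whose planted effect meets the slRNA definition.

        Sub-24 h pulses qualify directly.  Sinusoids whose period divides
        24 h also qualify: all 24-hourly samples take identical values while
        intra-day samples differ (such genes are both slRNA and cycRNA).
        """
        out = set()
        for _, row in self.df.iterrows():
            p = json.loads(row["params"])
            if row["kind"] == "pulse" and p["duration_h"] < 24 and p["amplitude"] > 0:
                out.add(row["gene_id"])
            if row["kind"] == "sinusoid" and p["amplitude"] > 0:
                if 24.0 % p["period_h"] == 0:
                    out.add(row["gene_id"])
        return out

    def cycrna_truth(self, max_period_hours: float = 36.0) -> set:
        out = set()
        for _, row in self.df.iterrows():
            if row["kind"] != "sinusoid":
                continue
            p = json.loads(row["params"])
            if p["amplitude"] > 0 and p["period_h"] < max_period_hours:
                out.add(row["gene_id"])
        return out

    def blocks(self) -> dict:
        """Ordered member lists of planted co-expression blocks."""
        out: dict = {}
        for _, row in self.df.iterrows():
            if row["kind"] != "coexpression_block":
                continue
            p = json.loads(row["params"])
            out.setdefault(p["profile_id"], []).append(
                (p["member_index"], row["gene_id"])
            )
        return {k: [g for _, g in sorted(v)] for k, v in out.items()}

    def pairs(self) -> list:
        seen = set()
        out = []
        for _, row in self.df.iterrows():
            if row["kind"] != "bidirectional_pair":
                continue
            p = json.loads(row["params"])
            key = tuple(p["signal_genes"])
            if key not in seen:
                seen.add(key)
                out.append((key[0], key[1], p))
        return out

    def lagged_pairs(self) -> list:
        """(regulator, target, lag_hours, sign) for planted lagged targets."""
        out = []
        for _, row in self.df.iterrows():
            if row["kind"] != "lagged_target":
                continue
            p = json.loads(row["params"])
            out.append((p["regulator"], row["gene_id"], p["lag_h"], p.get("sign", 1)))
        return out

    # -------------------------------------------------------------------- io
    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "TruthTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"params": str}))


# ============================================================ effect profiles
def _logistic(t, amplitude, midpoint_h, rate_h):
    return amplitude / (1.0 + np.exp(-(t - midpoint_h) / rate_h))


def _raised_cosine(t, start_h, duration_h, amplitude):
    x = (np.asarray(t, dtype=float) - start_h) / duration_h
    inside = (x >= 0) & (x <= 1)
    out = np.zeros_like(x)
    out[inside] = 0.5 * amplitude * (1.0 - np.cos(2 * np.pi * x[inside]))
    return out


def _block_profile_fn(cfg: SimConfig, profile_id: int) -> Callable:
    """Smooth random log2 profile shared by a block, scaled to unit sd."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 911, profile_id]))
    grid = cfg.times
    raw = rng.normal(size=grid.size)
    # moving-average smoothing (window ~18 h) keeps the profile slow
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(np.convolve(raw, kernel, mode="same"), kernel, mode="same")
    smooth = (smooth - smooth.mean()) / max(smooth.std(), 1e-9)
    return lambda t: np.interp(t, grid, smooth)


def signal_effect_fn(cfg: SimConfig, sig: PlantedSignal, member: int) -> Callable:
    """Continuous-time log2 effect for one member gene of a signal."""
    p = sig.params
    if sig.kind in {"baseline"}:
        return lambda t: np.zeros_like(np.asarray(t, dtype=float))
    if sig.kind == "trend":
        return lambda t: _logistic(
            t, p["amplitude"], p.get("midpoint_h", 60.0), p.get("rate_h", 12.0)
        ) * p.get("sign", 1)
    if sig.kind == "pulse":
        return lambda t: _raised_cosine(t, p["start_h"], p["duration_h"], p["amplitude"])
    if sig.kind == "sinusoid":
        return lambda t: p["amplitude"] * np.cos(
            2 * np.pi * (np.asarray(t, dtype=float) - p.get("phase_h", 0.0)) / p["period_h"]
        )
    if sig.kind == "coexpression_block":
        fn = _block_profile_fn(cfg, p["profile_id"])
        amp = p.get("amplitude", 1.0)
        return lambda t: amp * fn(t)
    if sig.kind == "bidirectional_pair":
        base = signal_effect_fn(
            cfg, PlantedSignal(p["profile"]["kind"], (sig.gene_ids[member],), p["profile"]), 0
        )
        if member == 0:
            return base
        sign = p.get("sign", 1)
        lag = p.get("lag_h", 0.0)
        return lambda t: sign * base(np.asarray(t, dtype=float) - lag)
    raise ValueError(f"no direct effect for kind {sig.kind}")


def build_mean_profiles(cfg: SimConfig, gene_ids: Sequence[str]) -> pd.DataFrame:
    """Per-gene mean log2-CPM profile on the sampling grid."""
    t = cfg.times
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 303]))
    baseline = rng.normal(cfg.baseline_log2_cpm, cfg.baseline_sd, len(gene_ids))
    mu = pd.DataFrame(
        np.tile(baseline[:, None], (1, t.size)), index=pd.Index(gene_ids, name="gene_id"), columns=t
    )
    effect_fns: dict = {}
    lagged: list = []
    for sig in cfg.planted:
        if sig.kind == "lagged_target":
            lagged.append(sig)
            continue
        for i, g in enumerate(sig.gene_ids):
            fn = signal_effect_fn(cfg, sig, i)
            effect_fns[g] = fn
            mu.loc[g] = mu.loc[g].values + fn(t)
    for sig in lagged:
        reg = sig.params["regulator"]
        if reg not in effect_fns:
            raise ValueError(f"lagged_target regulator {reg!r} has no planted effect")
        fn = effect_fns[reg]
        lag = sig.params["lag_h"]
        sign = sig.params.get("sign", 1)
        for g in sig.gene_ids:
            mu.loc[g] = mu.loc[g].values + sign * fn(t - lag)
    return mu


# ================================================================= annotation
def _unit_list(cfg: SimConfig):
    """Split planted signals into placement units (pairs, blocks, singles)."""
    special, singles = [], []
    for sig in cfg.planted:
        if sig.kind == "bidirectional_pair":
            special.append(("pair", sig))
        elif sig.kind == "coexpression_block":
            special.append(("block", sig))
        else:
            for g in sig.gene_ids:
                biotype = sig.params.get("biotype", "protein_coding")
                singles.append((g, biotype))
    return special, singles


def simulate_annotation(cfg: SimConfig):
    """Lay planted and filler genes onto synthetic chromosomes.

    Pairs and blocks are placed as indivisible units; all planted units are
    spread evenly among filler genes so that no two planted signals sit on
    adjacent gene slots by construction.  Returns (gene table, truth table).
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 101]))
    special, singles = _unit_list(cfg)
    planted_gene_count = sum(
        2 if k == "pair" else len(s.gene_ids) for k, s in special
    ) + len(singles)
    n_fill = cfg.n_genes - planted_gene_count

    filler_ids = [f"GFILL{i:05d}" for i in range(n_fill)]
    lnc_choices = ["lincRNA", "antisense", "processed_transcript"]
    filler_bio = [
        rng.choice(lnc_choices) if rng.random() < cfg.filler_lncrna_frac else "protein_coding"
        for _ in filler_ids
    ]

    # planted units (pairs, blocks, planted singles) spread among fillers
    units = [(kind, sig) for kind, sig in special]
    units += [("single", g_b) for g_b in singles]
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    per_chrom_units: dict = {c: [] for c in chroms}
    for i, u in enumerate(units):
        per_chrom_units[chroms[i % len(chroms)]].append(u)

    # distribute fillers to equalize slot counts, then interleave
    def unit_size(u):
        kind = u[0]
        if kind == "pair":
            return 2
        if kind == "block":
            return len(u[1].gene_ids)
        return 1

    slots_special = {c: sum(unit_size(u) for u in per_chrom_units[c]) for c in chroms}
    total_slots = cfg.n_genes
    target = {c: total_slots // len(chroms) for c in chroms}
    for i in range(total_slots % len(chroms)):
        target[chroms[i]] += 1
    fill_per_chrom = {c: max(0, target[c] - slots_special[c]) for c in chroms}
    # adjust rounding so all fillers are used
    assigned = sum(fill_per_chrom.values())
    spill = n_fill - assigned
    ci = 0
    while spill != 0:
        c = chroms[ci % len(chroms)]
        if spill > 0:
            fill_per_chrom[c] += 1
            spill -= 1
        elif fill_per_chrom[c] > 0:
            fill_per_chrom[c] -= 1
            spill += 1
        ci += 1

    fill_iter = iter(zip(filler_ids, filler_bio))
    L, spacing = cfg.gene_length_bp, cfg.gene_spacing_bp
    jitter_max = int(0.15 * spacing)
    models: list[GeneModel] = []

    for c in chroms:
        specials_c = per_chrom_units[c]
        n_f = fill_per_chrom[c]
        order: list = [("filler", None)] * n_f
        # insert planted units at evenly spaced positions among the fillers
        s = len(specials_c)
        for i, unit in enumerate(reversed(specials_c)):
            j = s - 1 - i
            order.insert(round((j + 1) * n_f / (s + 1)), unit)

        pos = spacing
        for unit in order:
            kind = unit[0]
            if kind in {"filler", "single"}:
                if kind == "filler":
                    gid, biotype = next(fill_iter)
                    strand = "+" if rng.random() < 0.5 else "-"
                else:
                    gid, biotype = unit[1]
                    strand = "+" if rng.random() < 0.5 else "-"
                jit = int(rng.integers(-jitter_max, jitter_max + 1))
                start = pos + jit
                models.append(GeneModel(gid, c, start, start + L, strand, biotype))
                pos += spacing
            elif kind == "pair":
                sig = unit[1]
                d = int(sig.params["distance_bp"])
                bio = sig.params.get("biotypes", ["protein_coding", "protein_coding"])
                anchor = pos + L
                a, b = sig.gene_ids
                models.append(GeneModel(a, c, anchor - L, anchor, "-", bio[0]))
                models.append(GeneModel(b, c, anchor + d, anchor + d + L, "+", bio[1]))
                pos += 2 * spacing
            elif kind == "block":
                sig = unit[1]
                bio = sig.params.get("biotype", "protein_coding")
                for g in sig.gene_ids:
                    jit = int(rng.integers(-jitter_max, jitter_max + 1))
                    strand = "+" if rng.random() < 0.5 else "-"
                    start = pos + jit
                    models.append(GeneModel(g, c, start, start + L, strand, bio))
                    pos += spacing
        if cfg.chrom_lengths is not None:
            limit = cfg.chrom_lengths.get(c, 0)
            if pos > limit:
                raise PlacementError(
                    f"{c}: need {pos} bp for layout but chromosome is {limit} bp"
                )

    truth = TruthTable.from_signals(cfg.planted)
    genes = genes_to_frame(models)
    missing = set(truth.df["gene_id"]) - set(genes["gene_id"])
    if missing:
        raise PlacementError(f"planted genes not placed: {sorted(missing)[:5]}")
    return genes, truth


# ===================================================================== counts
def simulate_counts(cfg: SimConfig, genes: pd.DataFrame, truth: TruthTable | None = None):
    """Draw negative-binomial counts around the planted mean CPM profiles.

    Both replicates share each gene's mean log2 profile; replicate-level
    biological noise (sd = ``noise_sd`` log2 units) and NB sampling noise are
    independent.  Library sizes are log-normal around ``library_size_mean``.
    Returns (experiment, truth table).
    """
    cfg.validate()
    mu = build_mean_profiles(cfg, list(genes["gene_id"]))
    t = cfg.times
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 202]))

    n_samples = cfg.n_timepoints * cfg.n_replicates
    if cfg.library_size_cv > 0:
        sigma2 = np.log1p(cfg.library_size_cv**2)
        lib = rng.lognormal(
            np.log(cfg.library_size_mean) - sigma2 / 2, np.sqrt(sigma2), n_samples
        )
    else:
        lib = np.full(n_samples, float(cfg.library_size_mean))

    reps = [str(r + 1) for r in range(cfg.n_replicates)]
    eps = {
        r: rng.normal(0.0, cfg.noise_sd, size=mu.shape) if cfg.noise_sd > 0 else 0.0
        for r in reps
    }

    cols, meta_rows, data = [], [], []
    si = 0
    for ti, hours in enumerate(t):
        for r in reps:
            noise = eps[r][:, ti] if cfg.noise_sd > 0 else 0.0
            log2cpm = mu.iloc[:, ti].values + noise
            m = np.power(2.0, log2cpm) / 1e6 * lib[si]
            if cfg.nb_dispersion == 0:
                draws = rng.poisson(m)
            else:
                n_nb = 1.0 / cfg.nb_dispersion
                p_nb = n_nb / (n_nb + m)
                draws = rng.negative_binomial(n_nb, p_nb)
            sid = sample_name(hours, r)
            cols.append(sid)
            meta_rows.append((sid, float(hours), r))
            data.append(draws)
            si += 1

    counts = pd.DataFrame(
        np.column_stack(data), index=mu.index.copy(), columns=cols
    )
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "time_hours", "replicate"])
    meta = meta.set_index("sample_id")
    expt = TimeCourseExperiment(counts, meta)
    if truth is None:
        truth = TruthTable.from_signals(cfg.planted)
    return expt, truth


def simulate_study(cfg: SimConfig):
    """Annotation + counts + truth in one call."""
    genes, truth = simulate_annotation(cfg)
    expt, _ = simulate_counts(cfg, genes, truth)
    return expt, genes, truth
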