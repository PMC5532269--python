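"""Canned simulation scenarios reproducing the emulated study conditions.

Each builder returns a :class:`~teb.simulate.SimConfig` whose planted signals
define the ground truth for one analysis stage (or, for
:func:`default_study`, all stages at once).  Magnitudes follow the package's
standard test conditions: pulse amplitude 1.5 log2 units, sinusoid amplitude
1.0, per-replicate noise sd 0.2 log2 units — see docs/methods.md.
"""

from __future__ import annotations

from .simulate import PlantedSignal, SimConfig

WINDOWS = (0.0, 24.0, 48.0, 72.0, 96.0)


def _pulses(n: int, amplitude: float, duration_h: float = 18.0, prefix: str = "PULSE"):
    sigs = []
    for i in range(n):
        w = WINDOWS[i % len(WINDOWS)]
        sigs.append(
            PlantedSignal(
                "pulse",
                (f"{prefix}{i:04d}",),
                {"start_h": w + 3.0, "duration_h": duration_h, "amplitude": amplitude},
            )
        )
    return sigs


def _sinusoids(n: int, period_h: float, amplitude: float, prefix: str = "SIN"):
    return [
        PlantedSignal(
            "sinusoid",
            (f"{prefix}{i:04d}",),
            {
                "period_h": period_h,
                "amplitude": amplitude,
                "phase_h": period_h * i / max(n, 1),
            },
        )
        for i in range(n)
    ]


def _blocks(n: int, block_len: int, amplitude: float, prefix: str = "BLK"):
    return [
        PlantedSignal(
            "coexpression_block",
            tuple(f"{prefix}{b:02d}G{j}" for j in range(block_len)),
            {"profile_id": b, "amplitude": amplitude},
        )
        for b in range(n)
    ]


def slrna_scenario(seed: int, n_genes: int = 2000, n_pulses: int = 50,
                   amplitude: float = 1.5, noise_sd: float = 0.2) -> SimConfig:
    """Planted sub-24 h pulses among baseline genes (slRNA recovery)."""
    return SimConfig(
        n_genes=n_genes, seed=seed, noise_sd=noise_sd,
        planted=_pulses(n_pulses, amplitude),
    )


def cycrna_scenario(seed: int, n_genes: int = 2000, n_sinusoids: int = 30,
                    period_h: float = 24.0, amplitude: float = 1.0,
                    noise_sd: float = 0.2) -> SimConfig:
    """Planted 24 h sinusoids among aperiodic baseline controls."""
    return SimConfig(
        n_genes=n_genes, seed=seed, noise_sd=noise_sd,
        planted=_sinusoids(n_sinusoids, period_h, amplitude),
    )


def lag_scenario(seed: int, n_genes: int = 600, n_targets: int = 30,
                 lag_hours: float = 6.0, amplitude: float = 1.5,
                 noise_sd: float = 0.2) -> SimConfig:
    """One regulator plus targets tracking it at a fixed delay."""
    tf = PlantedSignal(
        "sinusoid", ("TF0000",), {"period_h": 48.0, "amplitude": amplitude, "phase_h": 0.0}
    )
    targets = [
        PlantedSignal(
            "lagged_target",
            (f"TGT{i:04d}",),
            {"regulator": "TF0000", "lag_h": lag_hours, "sign": 1},
        )
        for i in range(n_targets)
    ]
    return SimConfig(n_genes=n_genes, seed=seed, noise_sd=noise_sd, planted=[tf] + targets)


def block_scenario(seed: int, n_genes: int = 2000, n_blocks: int = 10,
                   block_len: int = 6, amplitude: float = 1.0,
                   noise_sd: float = 0.2) -> SimConfig:
    """Planted contiguous co-expression blocks among independent-noise fillers."""
    return SimConfig(
        n_genes=n_genes, seed=seed, noise_sd=noise_sd,
        planted=_blocks(n_blocks, block_len, amplitude),
    )


def pair_scenario(seed: int, n_genes: int = 400, n_pairs: int = 12,
                  noise_sd: float = 0.2) -> SimConfig:
    """Head-to-head bidirectional pairs at controlled TSS distances.

    Most pairs share a positively correlated trend; one is sign-flipped; two
    have the noncoding (minus-strand) member leading by 6 h so a driver can
    be assigned.
    """
    sigs = []
    for i in range(n_pairs):
        dist = 100 + (i * 1800) // max(n_pairs - 1, 1)
        params = {
            "distance_bp": dist,
            "profile": {"kind": "trend", "amplitude": 2.0,
                        "midpoint_h": 36.0 + 6.0 * (i % 5), "rate_h": 10.0},
            "sign": -1 if i == n_pairs - 1 else 1,
            "biotypes": ["antisense", "protein_coding"] if i % 3 == 0
            else ["protein_coding", "protein_coding"],
        }
        if i in (0, 3):
            params["lag_h"] = 6.0  # minus-strand (noncoding) member leads
        sigs.append(
            PlantedSignal("bidirectional_pair", (f"PAIRA{i:03d}", f"PAIRB{i:03d}"), params)
        )
    return SimConfig(n_genes=n_genes, seed=seed, noise_sd=noise_sd, planted=sigs)


def null_scenario(seed: int, n_genes: int = 5000, noise_sd: float = 0.2) -> SimConfig:
    """Global null for type-I calibration: no planted signal, homogeneous noise.

    Dispersion is set to zero and libraries made deep so that counting noise
    is negligible next to the log-scale biological noise — the regime where
    the moderated-t model assumptions hold and calibration is interpretable.
    """
    return SimConfig(
        n_genes=n_genes, seed=seed, noise_sd=noise_sd,
        nb_dispersion=0.0, library_size_mean=2e7, baseline_sd=0.5,
    )


def default_study(seed: int, n_genes: int = 2000) -> SimConfig:
    """The full multi-signal study used by the end-to-end pipeline.

    Plants every signal class at once: 40 slRNA pulses, 20 cycRNA sinusoids,
    a TF with 20 delayed targets, two candidate regulatory lncRNAs with
    delayed positive/negative target sets, 10 bidirectional pairs and
    8 contiguous co-expression blocks, with baseline fillers making up the
    remainder.
    """
    sigs: list[PlantedSignal] = []
    sigs += _pulses(40, 1.5)
    sigs += _sinusoids(20, 24.0, 1.0)
    sigs.append(
        PlantedSignal("sinusoid", ("TF0000",),
                      {"period_h": 48.0, "amplitude": 1.5, "phase_h": 0.0})
    )
    sigs += [
        PlantedSignal("lagged_target", (f"TGT{i:04d}",),
                      {"regulator": "TF0000", "lag_h": 6.0, "sign": 1})
        for i in range(20)
    ]
    for j, sign in enumerate((1, -1)):
        lnc = f"LNC{j:02d}"
        sigs.append(
            PlantedSignal("trend", (lnc,),
                          {"amplitude": 2.5, "midpoint_h": 30.0 + 24.0 * j,
                           "rate_h": 8.0, "biotype": "lincRNA"})
        )
        sigs += [
            PlantedSignal("lagged_target", (f"LNCT{j}{i:03d}",),
                          {"regulator": lnc, "lag_h": 6.0, "sign": sign})
            for i in range(8)
        ]
    sigs += pair_scenario(seed, n_pairs=10).planted
    sigs += _blocks(8, 6, 1.0)
    return SimConfig(n_genes=n_genes, seed=seed, noise_sd=0.2, planted=sigs)
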