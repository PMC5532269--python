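"""Bidirectional pairing, region scanning (vs brute force), TADs, modules."""

import numpy as np
import pandas as pd
import pytest

from teb.experiment import GeneModel, genes_to_frame
from teb.expression import cpm_normalize, filter_expressed
from teb.genome import (
    BidirectionalPair,
    assign_pair_driver,
    candidate_bidirectional,
    find_bidirectional_pairs,
    group_region_modules,
    pair_statistics,
    scan_coexpression_regions,
    tad_containment,
)
from teb.scenarios import block_scenario
from teb.simulate import simulate_study
from tests.conftest import make_experiment, profile_experiment


def _gene(gid, chrom, start, end, strand, biotype="protein_coding"):
    return GeneModel(gid, chrom, start, end, strand, biotype)


def brute_force_pairs(genes, max_dist=2000):
    """Independent all-pairs filter + greedy matching oracle."""
    cands = []
    rows = list(genes.itertuples(index=False))
    for a in rows:
        for b in rows:
            if a.gene_id == b.gene_id or a.chrom != b.chrom:
                continue
            if a.strand == "-" and b.strand == "+":
                d = b.tss - a.tss
                if 0 <= d < max_dist:
                    cands.append((a.gene_id, b.gene_id, d))
    cands.sort(key=lambda c: (c[2], c[0], c[1]))
    used, out = set(), []
    for a, b, d in cands:
        if a not in used and b not in used:
            used.update((a, b))
            out.append((a, b, d))
    return out


def brute_force_regions(ordered_ids, prof, min_genes=5, r_min=0.5):
    """Window enumeration oracle: all (i, j) with every adjacent link > r_min."""
    n = len(ordered_ids)
    link = []
    for i in range(n - 1):
        a = prof.loc[ordered_ids[i]].to_numpy()
        b = prof.loc[ordered_ids[i + 1]].to_numpy()
        link.append(np.corrcoef(a, b)[0, 1] > r_min)
    runs = []
    for i in range(n):
        for j in range(i + min_genes - 1, n):
            if all(link[i:j]):
                # maximal: cannot extend either way
                if (i == 0 or not link[i - 1]) and (j == n - 1 or not link[j]):
                    runs.append(tuple(ordered_ids[i : j + 1]))
    return set(runs)


class TestBidirectionalPairs:
    def _toy(self):
        return genes_to_frame(
            [
                _gene("m1", "chr1", 8000, 10000, "-"),  # tss 10000
                _gene("p1", "chr1", 11500, 13500, "+"),  # 1500 bp away -> pair
                _gene("m2", "chr1", 30000, 32000, "-"),  # tss 32000
                _gene("p2", "chr1", 32100, 34000, "-"),  # same strand: no pair
                _gene("m3", "chr2", 5000, 7000, "-"),  # tss 7000
                _gene("p3", "chr2", 9000, 11000, "+"),  # exactly 2000: excluded
            ]
        )

    def test_opposite_strand_within_window_paired(self):
        pairs = find_bidirectional_pairs(self._toy())
        assert [(p.gene_a, p.gene_b, p.tss_distance_bp) for p in pairs] == [
            ("m1", "p1", 1500)
        ]

    def test_same_strand_not_paired_and_2000_boundary_excluded(self):
        ids = {
            frozenset((p.gene_a, p.gene_b)) for p in find_bidirectional_pairs(self._toy())
        }
        assert frozenset(("m2", "p2")) not in ids
        assert frozenset(("m3", "p3")) not in ids
        # one bp closer is admitted
        genes = self._toy()
        genes.loc["p3", ["start", "end", "tss"]] = [8999, 10999, 8999]
        ids = {frozenset((p.gene_a, p.gene_b)) for p in find_bidirectional_pairs(genes)}
        assert frozenset(("m3", "p3")) in ids

    def test_greedy_matching_assigns_each_gene_once(self):
        genes = genes_to_frame(
            [
                _gene("m1", "chr1", 8000, 10000, "-"),
                _gene("p1", "chr1", 10100, 12000, "+"),  # 100 bp from m1
                _gene("p2", "chr1", 10900, 12900, "+"),  # 900 bp from m1
            ]
        )
        pairs = find_bidirectional_pairs(genes)
        assert len(pairs) == 1
        assert (pairs[0].gene_a, pairs[0].gene_b) == ("m1", "p1")

    def test_matches_all_pairs_brute_force_on_random_layouts(self):
        rng = np.random.default_rng(12)
        for trial in range(12):
            models = []
            pos = 1000
            for i in range(200):
                pos += int(rng.integers(200, 4000))
                strand = "+" if rng.random() < 0.5 else "-"
                chrom = f"chr{1 + i % 2}"
                models.append(_gene(f"g{trial}_{i}", chrom, pos, pos + int(rng.integers(500, 1500)), strand))
            genes = genes_to_frame(models)
            got = [(p.gene_a, p.gene_b, p.tss_distance_bp) for p in find_bidirectional_pairs(genes)]
            assert got == brute_force_pairs(genes)

    def test_mirror_invariance(self):
        # reflecting coordinates (and flipping strands) preserves the pair set
        genes = self._toy()
        L = 50000
        mirrored = genes.copy()
        mirrored["start"], mirrored["end"] = L - genes["end"], L - genes["start"]
        mirrored["strand"] = genes["strand"].map({"+": "-", "-": "+"})
        mirrored["tss"] = np.where(mirrored["strand"] == "+", mirrored["start"], mirrored["end"])
        p1 = {frozenset((p.gene_a, p.gene_b)) for p in find_bidirectional_pairs(genes)}
        p2 = {frozenset((p.gene_a, p.gene_b)) for p in find_bidirectional_pairs(mirrored)}
        assert p1 == p2


class TestPairStatistics:
    def test_identical_profiles_r_one_delta_zero(self):
        prof = np.tile(np.linspace(3, 6, 21), (3, 1))
        expt = cpm_normalize(profile_experiment(prof, np.arange(21) * 6.0, scale=2000))
        pair = BidirectionalPair("g0", "g1", 500, "coding-coding")
        table, _ = pair_statistics([pair], expt, seed=0)
        assert table["r"].iloc[0] == pytest.approx(1.0)
        assert table["abs_delta_median_logexpr"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_random_baseline_reproducible(self):
        rng = np.random.default_rng(13)
        prof = rng.normal(5, 0.5, (40, 21))
        expt = cpm_normalize(profile_experiment(prof, np.arange(21) * 6.0, scale=2000))
        pair = BidirectionalPair("g0", "g1", 500, "coding-coding")
        _, s1 = pair_statistics([pair], expt, seed=7, n_random=20)
        _, s2 = pair_statistics([pair], expt, seed=7, n_random=20)
        assert s1 == s2


class TestPairDriver:
    def _expt(self):
        t = np.arange(21) * 6.0
        lead = np.sin(2 * np.pi * t / 48.0) * 2 + 5
        follow = np.sin(2 * np.pi * (t - 6.0) / 48.0) * 2 + 5
        anti = 10 - lead
        # a dominant flat filler keeps library sizes stable so the planted
        # correlations survive CPM normalization
        filler = np.full(21, 14.0)
        prof = np.vstack([lead, follow, lead, anti, filler])
        return cpm_normalize(profile_experiment(prof, t, scale=5000))

    def test_leading_member_assigned_as_driver(self):
        expt = self._expt()
        pair = BidirectionalPair("g0", "g1", 500, "coding-noncoding")
        out = assign_pair_driver(pair, expt)
        assert out.driver == "a"
        assert out.driver_lag_hours == pytest.approx(6.0)

    def test_identical_profiles_no_driver(self):
        expt = self._expt()
        pair = BidirectionalPair("g0", "g2", 500, "coding-coding")
        assert assign_pair_driver(pair, expt).driver == "none"

    def test_anticorrelated_profiles_no_driver(self):
        expt = self._expt()
        pair = BidirectionalPair("g0", "g3", 500, "coding-coding")
        assert assign_pair_driver(pair, expt).driver == "none"


class TestRegionScan:
    def _layout(self, profiles, chrom="chr1"):
        models = [
            _gene(f"g{i}", chrom, 1000 + 10000 * i, 3000 + 10000 * i, "+")
            for i in range(profiles.shape[0])
        ]
        genes = genes_to_frame(models)
        # flat filler gene (absent from the annotation) stabilizes libraries
        filler = np.full((1, profiles.shape[1]), profiles.max() + 4.0)
        expt = cpm_normalize(
            profile_experiment(np.vstack([profiles, filler]), np.arange(21) * 6.0, scale=3000)
        )
        return genes, expt

    def test_six_linked_genes_form_one_region(self):
        t = np.arange(21) * 6.0
        shared = np.sin(2 * np.pi * t / 60.0) * 2 + 5
        rng = np.random.default_rng(14)
        prof = np.vstack([shared + rng.normal(0, 0.05, 21) for _ in range(6)])
        genes, expt = self._layout(prof)
        regions = scan_coexpression_regions(genes, expt, min_genes=5)
        assert len(regions) == 1
        assert regions[0].gene_ids == [f"g{i}" for i in range(6)]
        assert regions[0].n_genes == 6

    def test_broken_chain_keeps_only_long_enough_segment(self):
        t = np.arange(21) * 6.0
        a = np.sin(2 * np.pi * t / 60.0) * 2 + 5
        b = np.cos(2 * np.pi * t / 31.0) * 2 + 5  # uncorrelated with a
        rng = np.random.default_rng(15)
        prof = np.vstack(
            [a + rng.normal(0, 0.05, 21) for _ in range(5)]
            + [b + rng.normal(0, 0.05, 21) for _ in range(4)]
        )
        genes, expt = self._layout(prof)
        regions = scan_coexpression_regions(genes, expt, min_genes=5)
        assert len(regions) == 1
        assert regions[0].gene_ids == [f"g{i}" for i in range(5)]

    def test_exactly_five_genes_emitted_at_inclusive_boundary(self):
        t = np.arange(21) * 6.0
        shared = np.linspace(3, 7, 21)
        rng = np.random.default_rng(16)
        prof = np.vstack([shared + rng.normal(0, 0.05, 21) for _ in range(5)])
        genes, expt = self._layout(prof)
        assert len(scan_coexpression_regions(genes, expt, min_genes=5)) == 1

    def test_matches_brute_force_enumeration_on_random_layouts(self):
        rng = np.random.default_rng(17)
        t = np.arange(21) * 6.0
        for trial in range(15):
            n = int(rng.integers(10, 40))
            # mixture: some shared-profile stretches to create real runs
            prof = rng.normal(5, 0.5, size=(n, 21))
            start = int(rng.integers(0, max(n - 6, 1)))
            shared = np.sin(2 * np.pi * t / 60.0) * 2 + 5
            for j in range(start, min(start + 6, n)):
                prof[j] = shared + rng.normal(0, 0.1, 21)
            genes, expt = self._layout(prof)
            regions = scan_coexpression_regions(genes, expt, min_genes=5)
            got = {tuple(r.gene_ids) for r in regions}
            ordered = genes.sort_values("tss")["gene_id"].tolist()
            expected = brute_force_regions(ordered, expt.replicate_mean("logexpr"))
            assert got == expected

    def test_planted_blocks_recovered_with_exact_boundaries(self):
        expt, genes, truth = simulate_study(block_scenario(21, n_genes=800, n_blocks=4))
        expt = filter_expressed(cpm_normalize(expt))
        expressed = genes.loc[genes.index.intersection(expt.gene_ids)]
        regions = scan_coexpression_regions(expressed, expt)
        found = {tuple(r.gene_ids) for r in regions}
        for members in truth.blocks().values():
            assert tuple(members) in found or tuple(reversed(members)) in found


class TestTadContainment:
    def _regions(self):
        from teb.genome import CoexpressionRegion

        mk = lambda chrom, s, e: CoexpressionRegion(chrom, s, e, ["x"], pd.Series([0.0, 1.0]))
        return [mk("chr1", 100, 200), mk("chr1", 900, 1500), mk("chr9", 0, 10)]

    def test_containment_categories(self):
        tads = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 1000], "end": [1000, 2000]}
        )
        out = tad_containment(self._regions(), tads)
        assert list(out["status"]) == ["contained", "spans-boundary", "no-overlap"]

    def test_chromosome_naming_mismatch_raises(self):
        tads = pd.DataFrame({"chrom": ["1", "2"], "start": [0, 0], "end": [1000, 1000]})
        with pytest.raises(ValueError, match="naming"):
            tad_containment(self._regions()[:2], tads)


class TestRegionModules:
    def _mk_regions(self, profiles):
        from teb.genome import CoexpressionRegion

        t = np.arange(21) * 6.0
        return [
            CoexpressionRegion("chr1", i * 1000, i * 1000 + 500, [f"r{i}"],
                               pd.Series(p, index=t))
            for i, p in enumerate(profiles)
        ]

    def test_up_and_down_families_give_two_modules_with_trends(self):
        t = np.arange(21) * 6.0
        up = np.linspace(0, 2, 21)
        rng = np.random.default_rng(18)
        regions = self._mk_regions(
            [up + rng.normal(0, 0.05, 21) for _ in range(3)]
            + [-up + rng.normal(0, 0.05, 21) for _ in range(3)]
        )
        out = group_region_modules(regions)
        assert out["module_id"].nunique() == 2
        trends = out.groupby("module_id")["trend"].first()
        assert set(trends) == {"increasing", "decreasing"}

    def test_single_region_single_module(self):
        regions = self._mk_regions([np.linspace(0, 1, 21)])
        out = group_region_modules(regions)
        assert list(out["module_id"]) == [0]

    def test_membership_invariant_to_input_order(self):
        t = np.arange(21) * 6.0
        rng = np.random.default_rng(19)
        up = np.linspace(0, 2, 21)
        profs = [up + rng.normal(0, 0.05, 21) for _ in range(3)] + [
            -up + rng.normal(0, 0.05, 21) for _ in range(2)
        ]
        r1 = self._mk_regions(profs)
        r2 = self._mk_regions(profs[::-1])
        m1 = group_region_modules(r1).set_index("region_index")["module_id"]
        m2 = group_region_modules(r2).set_index("region_index")["module_id"]
        # partition structure identical after reversing indices
        part1 = {frozenset(m1.index[m1 == k]) for k in m1.unique()}
        part2 = {
            frozenset(len(profs) - 1 - i for i in m2.index[m2 == k]) for k in m2.unique()
        }
        assert part1 == part2
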