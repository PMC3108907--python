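"""Hierarchical AMOVA: oracle checks, Phi statistics, permutation tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mitolineage import (
    SampleTable,
    amova,
    pairwise_phi_pt,
    permutation_test,
    phi_from_components,
)
from mitolineage.amova import _one_level_phi
from mitolineage.diversity import DistanceMatrix


def _dm(labels, d):
    d = np.asarray(d, dtype=float)
    z = np.zeros_like(d)
    return DistanceMatrix(list(labels), d, "k2p", z, z)


def _table(assign):
    """assign: sample -> (subspecies, population)."""
    return SampleTable(
        pd.DataFrame(
            {
                "sample": list(assign),
                "subspecies": [v[0] for v in assign.values()],
                "population": [v[1] for v in assign.values()],
            }
        )
    )


def brute_force_ss(d, pop_of, region_of):
    """Independent sums-of-squares oracle by direct enumeration."""
    n = len(pop_of)
    d2 = np.asarray(d) ** 2
    ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_wp = 0.0
    for p in set(pop_of):
        idx = [i for i in range(n) if pop_of[i] == p]
        ss_wp += sum(
            d2[i, j] for i in idx for j in idx if i < j
        ) / len(idx)
    ss_wg = 0.0
    for g in set(region_of):
        idx = [i for i in range(n) if region_of[i] == g]
        ss_wg += sum(
            d2[i, j] for i in idx for j in idx if i < j
        ) / len(idx)
    return ss_total, ss_total - ss_wg, ss_wg - ss_wp, ss_wp


@pytest.fixture
def random_design():
    rng = np.random.default_rng(7)
    # 3 regions, 6 populations, unequal sizes
    assign = {}
    sizes = [(("r1", "p1"), 3), (("r1", "p2"), 2), (("r2", "p3"), 4),
             (("r2", "p4"), 2), (("r3", "p5"), 3), (("r3", "p6"), 5)]
    k = 0
    for (region, pop), n in sizes:
        for _ in range(n):
            assign[f"s{k}"] = (region, pop)
            k += 1
    n = k
    x = rng.normal(size=(n, 4)) + np.array(
        [hash(assign[f"s{i}"][1]) % 5 for i in range(n)]
    )[:, None]
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0)
    return _dm([f"s{i}" for i in range(n)], d), _table(assign), assign


class TestComponents:
    def test_ss_additivity_and_oracle(self, random_design):
        dm, table, assign = random_design
        res = amova(dm, table)
        pop_of = [assign[s][1] for s in dm.labels]
        region_of = [assign[s][0] for s in dm.labels]
        ss_total, ss_ag, ss_ap, ss_wp = brute_force_ss(dm.d, pop_of, region_of)
        assert res.ss["among_regions"] == pytest.approx(ss_ag, rel=1e-9)
        assert res.ss["among_pops"] == pytest.approx(ss_ap, rel=1e-9)
        assert res.ss["within_pops"] == pytest.approx(ss_wp, rel=1e-9)
        assert sum(res.ss.values()) == pytest.approx(ss_total, rel=1e-9)
        assert sum(res.df.values()) == dm.n - 1

    def test_balanced_design_closed_form(self):
        """Equal sizes: coefficients collapse to n, n, n*P/G textbook forms."""
        rng = np.random.default_rng(3)
        n_per, pops_per_region, regions = 3, 2, 2
        assign = {}
        k = 0
        for g in range(regions):
            for p in range(pops_per_region):
                for _ in range(n_per):
                    assign[f"s{k}"] = (f"r{g}", f"p{g}{p}")
                    k += 1
        x = rng.normal(size=(k, 3))
        d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        np.fill_diagonal(d, 0)
        dm = _dm(list(assign), d)
        res = amova(dm, _table(assign))
        ms = res.ms
        # textbook: sigma2_c = MS_w; sigma2_b = (MS_p - MS_w)/n;
        # sigma2_a = (MS_g - MS_p)/(n * pops_per_region)
        s2c = ms["within_pops"]
        s2b = (ms["among_pops"] - s2c) / n_per
        s2a = (ms["among_regions"] - ms["among_pops"]) / (n_per * pops_per_region)
        assert res.sigma2["c"] == pytest.approx(s2c, rel=1e-9)
        assert res.sigma2["b"] == pytest.approx(s2b, rel=1e-9)
        assert res.sigma2["a"] == pytest.approx(s2a, rel=1e-9)

    def test_perfect_differentiation_phi_pt_one(self):
        # 2 populations x 2 samples, d=0 within, d=1 across
        d = np.array(
            [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], dtype=float
        )
        dm = _dm(list("abcd"), d)
        table = _table({"a": ("r", "p1"), "b": ("r", "p1"),
                        "c": ("r", "p2"), "d": ("r", "p2")})
        res = amova(dm, table)
        assert res.phi["phi_pt"] == pytest.approx(1.0)
        assert "single_region_phi_rt_undefined" in res.flags

    def test_all_equal_distances_small_phi(self):
        n = 8
        d = np.ones((n, n)) - np.eye(n)
        labels = [f"s{i}" for i in range(n)]
        assign = {s: ("r1" if i < 4 else "r2", f"p{i // 2}") for i, s in enumerate(labels)}
        res = amova(_dm(labels, d), _table(assign))
        # exchangeable distances: expected Phi_PT near zero (may be negative)
        assert res.phi["phi_pt"] < 0.15
        assert "negative_variance_component" in res.flags or res.phi["phi_pt"] >= 0

    def test_printed_component_phi(self):
        phi = phi_from_components(0.00012, 0.00008, 0.00023)
        assert phi["phi_pt"] == pytest.approx(0.4649, abs=1e-3)
        assert phi["phi_rt"] == pytest.approx(0.2791, abs=1e-2)
        assert phi["phi_pr"] == pytest.approx(0.2581, abs=1e-2)


class TestPermutation:
    def test_flat_distances_give_p_near_one(self):
        n = 8
        d = np.ones((n, n)) - np.eye(n)
        labels = [f"s{i}" for i in range(n)]
        assign = {s: ("r1" if i < 4 else "r2", f"p{i // 2}") for i, s in enumerate(labels)}
        p = permutation_test(_dm(labels, d), _table(assign), "phi_pt", 200, seed=1)
        assert p > 0.9

    def test_determinism_under_fixed_seed(self, random_design):
        dm, table, _ = random_design
        p1 = permutation_test(dm, table, "phi_pr", 300, seed=11)
        p2 = permutation_test(dm, table, "phi_pr", 300, seed=11)
        assert p1 == p2

    def test_exhaustive_enumeration_matches_estimate(self):
        """2x2 perfectly differentiated design vs all label relabelings."""
        d = np.array(
            [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], dtype=float
        )
        dm = _dm(list("abcd"), d)
        table = _table({"a": ("r", "p1"), "b": ("r", "p1"),
                        "c": ("r", "p2"), "d": ("r", "p2")})
        codes = np.array([0, 0, 1, 1])
        d2 = d**2
        observed = _one_level_phi(d2, codes)
        hits = sum(
            _one_level_phi(d2, np.array(perm)) >= observed - 1e-12
            for perm in itertools.permutations(codes)
        )
        exact = hits / 24  # = 1/3: only the two faithful labelings reach Phi = 1
        assert exact == pytest.approx(1 / 3)
        p = permutation_test(dm, table, "phi_pt", 3000, seed=5)
        assert p == pytest.approx(exact, abs=0.03)


class TestPairwise:
    def test_fixed_differences_no_within_variation(self):
        d = np.array(
            [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], dtype=float
        )
        dm = _dm(list("abcd"), d)
        table = _table({"a": ("r", "p1"), "b": ("r", "p1"),
                        "c": ("r", "p2"), "d": ("r", "p2")})
        out = pairwise_phi_pt(dm, table, n_perm=50, seed=2)
        assert out.loc["p2", "p1"] == pytest.approx(1.0)

    def test_monomorphic_identical_pair_reported_zero(self):
        d = np.zeros((4, 4))
        dm = _dm(list("abcd"), d)
        table = _table({"a": ("r", "p1"), "b": ("r", "p1"),
                        "c": ("r", "p2"), "d": ("r", "p2")})
        out = pairwise_phi_pt(dm, table, n_perm=10, seed=0)
        assert out.loc["p2", "p1"] == 0.0
        assert np.isnan(out.loc["p1", "p2"])  # p undefined, flagged

    def test_null_calibration_and_monotonicity(self):
        """Phi ~ 0 under exchangeable labels; increases with divergence depth."""
        from mitolineage.simulate import (
            PopulationSpec,
            SimulationConfig,
            evolve_alignment,
            simulate_tree,
        )
        from mitolineage.io import Partition, PartitionMap
        from mitolineage import pairwise_distances

        parts = PartitionMap([Partition("r", "rRNA", 1, 2000)], 2000)

        def replicate(depth_pop, seed):
            cfg = SimulationConfig(
                populations=[PopulationSpec("A", "x", 6), PopulationSpec("B", "x", 6)],
                partitions=parts,
                class_rates={"rRNA": 0.02},
                depth_within=0.2,
                depth_population=depth_pop,
                depth_root=depth_pop,
            )
            tree = simulate_tree(cfg, seed)
            aln, _ = evolve_alignment(tree, cfg, seed + 1)
            dm = pairwise_distances(aln, "p")
            labels = aln.samples
            # null: labels assigned independently of ancestry
            rng = np.random.default_rng(seed)
            shuffled = rng.permutation(labels)
            null_assign = {s: ("x", "p1" if i < 6 else "p2")
                           for i, s in enumerate(shuffled)}
            null_phi = _one_level_phi(
                dm.d**2,
                np.array([0 if null_assign[s][1] == "p1" else 1 for s in labels]),
            )
            true_assign = {s: ("x", s.split("_")[0]) for s in labels}
            true_phi = _one_level_phi(
                dm.d**2,
                np.array([0 if true_assign[s][1] == "A" else 1 for s in labels]),
            )
            return null_phi, true_phi

        nulls, sweep = [], {0.25: [], 0.6: [], 1.5: []}
        for seed in range(0, 40, 2):
            null_phi, _ = replicate(0.25, seed)
            nulls.append(null_phi)
            for depth in sweep:
                sweep[depth].append(replicate(depth, seed)[1])
        assert abs(float(np.mean(nulls))) < 0.1
        means = [float(np.mean(sweep[d])) for d in sorted(sweep)]
        assert means[0] < means[1] < means[2]
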