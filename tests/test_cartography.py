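import itertools

import numpy as np
import pandas as pd
import pytest

import funcarto as fc
from funcarto.cartography import NullDistributions

from oracles import allegiance_counting


def _allegiance(P, node_ids=None):
    return fc.AllegianceMatrix(P, n_optimizations=1, n_slices=1,
                               node_ids=node_ids or [])


def _ensemble_from_labels(label_matrices):
    parts = [fc.Partition(np.asarray(L)) for L in label_matrices]
    return fc.PartitionEnsemble(
        partitions=parts,
        qualities=np.zeros(len(parts)),
        seeds=list(range(len(parts))),
        gamma=1.0,
        omega=0.0,
    )


class TestModuleAllegiance:
    def test_identical_partitions_give_binary_allegiance(self):
        L = [[0, 0], [0, 0], [1, 1]]
        P = fc.module_allegiance(_ensemble_from_labels([L, L]))
        expected = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=float)
        assert np.array_equal(P.P, expected)

    def test_half_cooccurrence_across_runs(self):
        together = [[0, 0], [0, 0]]
        apart = [[0, 0], [1, 1]]
        P = fc.module_allegiance(_ensemble_from_labels([together, apart]))
        assert P.P[0, 1] == pytest.approx(0.5)

    def test_matches_counting_oracle(self, small_ensemble):
        P = fc.module_allegiance(small_ensemble)
        direct = allegiance_counting(small_ensemble.partitions)
        assert np.allclose(P.P, direct, atol=1e-12)

    def test_invariants_on_detected_ensembles(self, small_ensemble):
        P = fc.module_allegiance(small_ensemble)
        assert np.array_equal(P.P, P.P.T)
        assert P.P.min() >= 0.0 and P.P.max() <= 1.0
        assert np.all(np.diag(P.P) == 1.0)


class TestFlexibility:
    @pytest.mark.parametrize(
        "labels,expected",
        [
            ([1, 1, 1, 1, 1], 0.0),
            ([0, 1, 0, 1, 0], 1.0),
            ([1, 1, 2, 2, 3], 0.5),
        ],
    )
    def test_transition_counting(self, labels, expected):
        part = fc.Partition(np.array([labels]))
        assert fc.flexibility(part).f[0] == pytest.approx(expected)

    def test_ensemble_mean(self):
        still = [[0, 0, 0]]
        moving = [[0, 1, 0]]
        ens = _ensemble_from_labels([still, moving])
        assert fc.ensemble_flexibility(ens).f[0] == pytest.approx(0.5)

    def test_single_slice_rejected(self):
        with pytest.raises(fc.ValidationError, match="two slices"):
            fc.flexibility(fc.Partition(np.array([[0], [1]])))

    def test_bounds(self, small_ensemble):
        f = fc.ensemble_flexibility(small_ensemble)
        assert f.f.min() >= 0.0 and f.f.max() <= 1.0
        assert f.network_mean == pytest.approx(f.f.mean())


class TestRegionCoefficients:
    def test_all_ones_allegiance(self):
        P = _allegiance(np.ones((4, 4)))
        systems = fc.SystemMap([f"n{i}" for i in range(4)],
                               ["A", "A", "B", "B"])
        R, I = fc.region_coefficients(P, systems)
        assert np.allclose(R, 1.0)
        assert np.allclose(I, 1.0)

    def test_identity_allegiance(self):
        P = _allegiance(np.eye(4))
        systems = fc.SystemMap([f"n{i}" for i in range(4)],
                               ["A", "A", "B", "B"])
        R, I = fc.region_coefficients(P, systems)
        assert np.allclose(R, 0.5)  # only the self term survives, n_S = 2
        assert np.allclose(I, 0.0)

    def test_conservation_identity(self, rng):
        """n_S R_i + (N - n_S) I_i equals the row sum of P exactly."""
        M = rng.random((6, 6))
        P_mat = (M + M.T) / 2
        np.fill_diagonal(P_mat, 1.0)
        P = _allegiance(np.clip(P_mat, 0, 1))
        systems = fc.SystemMap([f"n{i}" for i in range(6)],
                               ["A", "A", "B", "B", "B", "C"])
        R, I = fc.region_coefficients(P, systems)
        sizes = {"A": 2, "B": 3, "C": 1}
        for i, sys in enumerate(systems.assignment):
            n_S = sizes[sys]
            lhs = n_S * R.iloc[i] + (6 - n_S) * I.iloc[i]
            assert lhs == pytest.approx(P.P[i].sum(), abs=1e-12)

    def test_exclude_self_variant(self, rng):
        M = rng.random((4, 4))
        P_mat = np.clip((M + M.T) / 2, 0, 1)
        np.fill_diagonal(P_mat, 1.0)
        P = _allegiance(P_mat)
        systems = fc.SystemMap(list("abcd"), ["A", "A", "B", "B"])
        R_in, _ = fc.region_coefficients(P, systems, exclude_self=False)
        R_ex, _ = fc.region_coefficients(P, systems, exclude_self=True)
        # inclusive mean = (1 + (n_S - 1) * exclusive mean) / n_S
        assert np.allclose(R_in, (1 + R_ex) / 2)

    def test_whole_network_system_rejected(self):
        P = _allegiance(np.eye(3))
        systems = fc.SystemMap(list("abc"), ["A", "A", "A"])
        with pytest.raises(fc.ValidationError, match="undefined"):
            fc.region_coefficients(P, systems)


class TestSystemCoefficients:
    def test_all_ones(self):
        P = _allegiance(np.ones((4, 4)))
        systems = fc.SystemMap(list("abcd"), ["A", "A", "B", "B"])
        R, pair, I = fc.system_coefficients(P, systems)
        assert np.allclose(R, 1.0)
        assert np.allclose(I, 1.0)

    def test_block_diagonal(self):
        P_mat = np.zeros((4, 4))
        P_mat[:2, :2] = 1.0
        P_mat[2:, 2:] = 1.0
        P = _allegiance(P_mat)
        systems = fc.SystemMap(list("abcd"), ["A", "A", "B", "B"])
        R, pair, I = fc.system_coefficients(P, systems)
        assert np.allclose(R, 1.0)
        assert np.allclose(I, 0.0)

    def test_overall_integration_is_weighted_pairwise_average(self, rng):
        M = rng.random((9, 9))
        P_mat = np.clip((M + M.T) / 2, 0, 1)
        np.fill_diagonal(P_mat, 1.0)
        P = _allegiance(P_mat)
        systems = fc.SystemMap(
            [f"n{i}" for i in range(9)],
            ["A"] * 2 + ["B"] * 3 + ["C"] * 4,
        )
        R, pair, I = fc.system_coefficients(P, systems)
        sizes = {"A": 2, "B": 3, "C": 4}
        for sys in ["A", "B", "C"]:
            others = [s for s in sizes if s != sys]
            weights = np.array([sizes[o] for o in others], dtype=float)
            vals = np.array([pair.loc[sys, o] for o in others])
            expected = (weights * vals).sum() / weights.sum()
            assert I[sys] == pytest.approx(expected, abs=1e-12)


class TestPermutationNull:
    def test_all_ones_degenerate(self):
        P = _allegiance(np.ones((4, 4)))
        systems = fc.SystemMap(list("abcd"), ["A", "A", "B", "B"])
        null = fc.permutation_null(P, systems, n_perm=200, seed=0)
        assert np.allclose(null.recruitment, 1.0)
        assert np.allclose(null.integration, 1.0)

    def test_matches_exhaustive_assignment_average(self, rng):
        """Sampled null mean agrees with the exact average over all
        distinct 2+2 assignments of 4 nodes."""
        M = rng.random((4, 4))
        P_mat = np.clip((M + M.T) / 2, 0, 1)
        np.fill_diagonal(P_mat, 1.0)
        P = _allegiance(P_mat)
        systems = fc.SystemMap(list("abcd"), ["A", "A", "B", "B"])
        exact_R = {"A": [], "B": []}
        for perm in itertools.permutations(range(4)):
            for sys, idx in (("A", perm[:2]), ("B", perm[2:])):
                block = P_mat[np.ix_(idx, idx)]
                exact_R[sys].append(block.sum() / 4.0)
        null = fc.permutation_null(P, systems, n_perm=4000, seed=1)
        for k, sys in enumerate(["A", "B"]):
            exact = np.mean(exact_R[sys])
            sampled = null.recruitment[:, k].mean()
            mc_sd = np.std(exact_R[sys]) / np.sqrt(4000)
            assert abs(sampled - exact) < 5 * mc_sd + 1e-12

    def test_equal_size_systems_exchangeable_under_null(self, small_ensemble, noisy_planted):
        scenario, _, _ = noisy_planted
        P = fc.module_allegiance(small_ensemble)
        null = fc.permutation_null(P, scenario.system_map, n_perm=800, seed=3)
        means = null.recruitment.mean(axis=0)
        assert means.max() - means.min() < 0.05

    def test_deterministic_given_seed(self, rng):
        M = rng.random((6, 6))
        P_mat = np.clip((M + M.T) / 2, 0, 1)
        np.fill_diagonal(P_mat, 1.0)
        P = _allegiance(P_mat)
        systems = fc.SystemMap([f"n{i}" for i in range(6)],
                               ["A"] * 3 + ["B"] * 3)
        n1 = fc.permutation_null(P, systems, n_perm=150, seed=9)
        n2 = fc.permutation_null(P, systems, n_perm=150, seed=9)
        assert np.array_equal(n1.recruitment, n2.recruitment)
        assert np.array_equal(n1.integration, n2.integration)

    def test_small_replicate_count_warns(self):
        P = _allegiance(np.eye(4))
        systems = fc.SystemMap(list("abcd"), ["A", "A", "B", "B"])
        with pytest.warns(UserWarning, match="small for stable"):
            fc.permutation_null(P, systems, n_perm=50, seed=0)


def _null_from_samples(systems, R, I, pairwise=None):
    return NullDistributions(systems, np.asarray(R, float),
                             np.asarray(I, float), pairwise)


class TestClassifyRoles:
    def test_role_grid(self, rng):
        systems = ["hi", "mid", "lo"]
        R_null = rng.normal(0.5, 0.01, size=(500, 3))
        I_null = rng.normal(0.5, 0.01, size=(500, 3))
        null = _null_from_samples(systems, R_null, I_null)
        R = pd.Series([0.9, 0.5, 0.1], index=systems)
        I = pd.Series([0.1, 0.5, 0.9], index=systems)
        roles = fc.classify_roles(R, I, null)
        assert roles.loc["hi", "role"] == "stable loner"
        assert roles.loc["mid", "role"] == "unstable connector"
        assert roles.loc["lo", "role"] == "ephemeral integrator"

    def test_both_above_is_stable_integrator(self, rng):
        systems = ["s"]
        null = _null_from_samples(
            ["s"], rng.normal(0.5, 0.01, (500, 1)), rng.normal(0.5, 0.01, (500, 1))
        )
        roles = fc.classify_roles(
            pd.Series([0.95], index=systems), pd.Series([0.95], index=systems), null
        )
        assert roles.loc["s", "role"] == "stable integrator"


class TestEdgeFlags:
    def test_all_equal_pairwise_is_ns(self, rng):
        systems = ["A", "B", "C"]
        pair = pd.DataFrame(0.4 * np.ones((3, 3)), index=systems, columns=systems)
        null_pairs = 0.4 + rng.normal(0, 0.02, size=(400, 3, 3))
        null_pairs = (null_pairs + null_pairs.transpose(0, 2, 1)) / 2
        null = _null_from_samples(systems, np.zeros((400, 3)),
                                  np.zeros((400, 3)), null_pairs)
        flags = fc.flag_integration_edges(pair, null)
        assert (flags.loc["A", "B"], flags.loc["A", "C"], flags.loc["B", "C"]) == (
            "ns", "ns", "ns",
        )

    def test_extreme_pair_flagged(self, rng):
        systems = ["A", "B", "C"]
        # off-diagonal values 0.6 / 0.0 / 0.3 -> mean edge weight 0.3,
        # so B-C sits exactly at the mean while A-B and A-C are extreme
        vals = np.full((3, 3), 0.3)
        vals[0, 1] = vals[1, 0] = 0.6
        vals[0, 2] = vals[2, 0] = 0.0
        pair = pd.DataFrame(vals, index=systems, columns=systems)
        null_pairs = 0.3 + rng.normal(0, 0.01, size=(400, 3, 3))
        null = _null_from_samples(systems, np.zeros((400, 3)),
                                  np.zeros((400, 3)), null_pairs)
        flags = fc.flag_integration_edges(pair, null)
        assert flags.loc["A", "B"] == "stronger"
        assert flags.loc["A", "C"] == "weaker"
        assert flags.loc["B", "C"] == "ns"


class TestSystemMapValidation:
    def test_duplicate_nodes_rejected(self):
        with pytest.raises(fc.ValidationError, match="duplicate"):
            fc.SystemMap(["a", "a"], ["A", "B"])

    def test_alignment_errors(self):
        smap = fc.SystemMap(["a", "b"], ["A", "B"])
        with pytest.raises(fc.ValidationError, match="absent from system map"):
            smap.reordered(["a", "b", "c"])
        with pytest.raises(fc.ValidationError, match="absent from matrices"):
            smap.reordered(["a"])

    def test_sizes_and_order(self):
        smap = fc.SystemMap(["a", "b", "c"], ["X", "Y", "X"])
        assert smap.systems == ["X", "Y"]
        assert smap.sizes == {"X": 2, "Y": 1}


class TestEndToEnd:
    def test_planted_systems_recruited_above_null(self, noisy_planted):
        scenario, net, _ = noisy_planted
        ens = fc.run_ensemble(net, n_runs=10, seed=1)
        result = fc.functional_cartography(ens, scenario.system_map,
                                           n_perm=400, seed=2)
        for sys in scenario.system_map.systems:
            assert result.roles.loc[sys, "recruitment_class"] == "stable"
            assert result.roles.loc[sys, "integration_class"] == "loner"

    def test_result_serializes(self, noisy_planted):
        scenario, net, _ = noisy_planted
        ens = fc.run_ensemble(net, n_runs=5, seed=1)
        result = fc.functional_cartography(ens, scenario.system_map,
                                           n_perm=150, seed=2)
        d = result.to_dict()
        assert set(d["systems"]) == set(scenario.system_map.systems)
        for info in d["systems"].values():
            assert {"recruitment", "integration", "role"} <= set(info)
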