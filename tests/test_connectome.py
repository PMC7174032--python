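"""Connectome construction, control-referenced thresholding, subnetworks."""

import numpy as np
import pytest

from cognet import (
    Connectome,
    SubnetworkDefinition,
    apply_threshold,
    build_connectome,
    extract_subnetwork,
    fit_threshold_scheme,
    mean_fa_per_connection,
)
from cognet.connectome import ControlReferencedThreshold, DEFAULT_LEVELS

from oracles import random_weighted_graph


class TestMeanFA:
    def test_two_voxel_mean(self):
        fa = np.zeros((2, 2, 2))
        fa[0, 0, 0], fa[0, 0, 1] = 0.2, 0.4
        mask = np.zeros_like(fa)
        mask[0, 0, :] = 1
        out = mean_fa_per_connection(fa, {(0, 1): mask})
        assert out[(0, 1)] == pytest.approx(0.3)

    def test_empty_overlap_is_zero(self):
        fa = np.zeros((3, 3, 3))
        mask = np.ones_like(fa)
        assert mean_fa_per_connection(fa, {(0, 1): mask})[(0, 1)] == 0.0

    def test_matches_voxel_loop_oracle(self, rng):
        fa = rng.uniform(0, 1, (10, 10, 10))
        fa[fa < 0.3] = 0.0  # off-skeleton voxels
        masks = {
            (i, i + 1): (rng.random((10, 10, 10)) < 0.2).astype(int)
            for i in range(5)
        }
        out = mean_fa_per_connection(fa, masks)
        for key, mask in masks.items():
            vals = [
                fa[x, y, z]
                for x in range(10)
                for y in range(10)
                for z in range(10)
                if mask[x, y, z] and fa[x, y, z] > 0
            ]
            expected = float(np.mean(vals)) if vals else 0.0
            assert out[key] == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch_names_both_shapes(self):
        with pytest.raises(ValueError, match=r"\(2, 2\).*\(3, 3\)|\(3, 3\).*\(2, 2\)"):
            mean_fa_per_connection(np.zeros((3, 3)), {(0, 1): np.zeros((2, 2))})


class TestBuildConnectome:
    def test_fa_times_streamlines(self):
        s = np.array([[0, 100], [100, 0]])
        c = build_connectome({(0, 1): 0.5}, s)
        assert c.weights[0, 1] == pytest.approx(50.0)

    def test_zero_streamlines_zero_weight(self, rng):
        s = np.array([[0, 0, 3], [0, 0, 5], [3, 5, 0]])
        fa = np.full((3, 3), 0.7)
        np.fill_diagonal(fa, 0)
        c = build_connectome(fa, s)
        assert c.weights[0, 1] == 0.0
        assert c.weights[0, 2] == pytest.approx(2.1)

    def test_unit_streamlines_recover_fa(self, rng):
        fa = random_weighted_graph(rng, 5)
        s = 1 - np.eye(5)
        c = build_connectome(fa, s)
        np.testing.assert_allclose(c.weights, fa)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_connectome(np.full((2, 2), -0.1), np.ones((2, 2)) - np.eye(2))
        with pytest.raises(ValueError):
            build_connectome(np.zeros((2, 2)), -np.ones((2, 2)))


class TestThresholdScheme:
    def test_identical_controls_zero_sd(self, rng):
        w = random_weighted_graph(rng, 6)
        scheme = fit_threshold_scheme(np.stack([w, w]))
        assert np.all(scheme.ctrl_sd == 0)
        np.testing.assert_allclose(scheme.ctrl_mean, w)

    def test_mean_and_population_sd(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        b = np.array([[0.0, 3.0], [3.0, 0.0]])
        scheme = fit_threshold_scheme(np.stack([a, b]))
        assert scheme.ctrl_mean[0, 1] == pytest.approx(2.0)
        assert scheme.ctrl_sd[0, 1] == pytest.approx(1.0)

    def test_ten_levels_from_half_to_five(self):
        np.testing.assert_allclose(DEFAULT_LEVELS, np.arange(1, 11) * 0.5)
        assert len(DEFAULT_LEVELS) == 10

    def test_fewer_than_two_controls_error(self, rng):
        with pytest.raises(ValueError):
            fit_threshold_scheme(random_weighted_graph(rng, 4)[None])

    def test_mean_reproduced_from_built_connectomes(self, rng):
        s = np.round(random_weighted_graph(rng, 8) * 10)
        fas = [random_weighted_graph(rng, 8) for _ in range(5)]
        built = [build_connectome(fa, s) for fa in fas]
        scheme = fit_threshold_scheme(built)
        np.testing.assert_allclose(
            scheme.ctrl_mean, np.mean([c.weights for c in built], axis=0), atol=1e-12
        )


class TestApplyThreshold:
    def _toy(self):
        labels = ["a", "b", "c"]
        mu = np.zeros((3, 3))
        mu[0, 1] = mu[1, 0] = 2.0
        mu[0, 2] = mu[2, 0] = 4.0
        mu[1, 2] = mu[2, 1] = 6.0
        sd = (1 - np.eye(3))
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[0, 2] = w[2, 0] = 2.5
        w[1, 2] = w[2, 1] = 3.5
        return labels, mu, sd, w

    def test_hand_computed_cutoffs(self):
        labels, mu, sd, w = self._toy()
        from cognet.connectome import ThresholdScheme

        scheme = ThresholdScheme(mu, sd)
        out = apply_threshold(Connectome(labels, w), scheme, t=2.0)
        # cutoffs mu - 2*sd = {0, 2, 4}: kept 0.5>=0, 2.5>=2, dropped 3.5<4
        assert out.weights[0, 1] == 0.5
        assert out.weights[0, 2] == 2.5
        assert out.weights[1, 2] == 0.0

    def test_zero_sd_keeps_at_or_above_mean(self, rng):
        w = random_weighted_graph(rng, 6)
        scheme = fit_threshold_scheme(np.stack([w, w]))  # sd 0, mean w
        out = apply_threshold(Connectome([f"n{i}" for i in range(6)], w), scheme, 3.0)
        np.testing.assert_allclose(out.weights, w)

    def test_negative_cutoffs_keep_everything(self, rng):
        stack = np.stack([random_weighted_graph(rng, 6) for _ in range(4)])
        scheme = fit_threshold_scheme(stack)
        c = Connectome([f"n{i}" for i in range(6)], stack[0])
        out = apply_threshold(c, scheme, t=1e6)
        np.testing.assert_allclose(out.weights, c.weights)

    def test_larger_level_keeps_superset_of_edges(self, rng):
        stack = np.stack([random_weighted_graph(rng, 10) for _ in range(6)])
        scheme = fit_threshold_scheme(stack)
        c = Connectome([f"n{i}" for i in range(10)], random_weighted_graph(rng, 10))
        strict = apply_threshold(c, scheme, 0.5).weights > 0
        liberal = apply_threshold(c, scheme, 5.0).weights > 0
        assert np.all(liberal[strict])  # strict edge set is a subset

    def test_idempotent_at_fixed_level(self, rng):
        stack = np.stack([random_weighted_graph(rng, 8) for _ in range(5)])
        scheme = fit_threshold_scheme(stack)
        c = Connectome([f"n{i}" for i in range(8)], random_weighted_graph(rng, 8))
        once = apply_threshold(c, scheme, 2.5)
        twice = apply_threshold(once, scheme, 2.5)
        np.testing.assert_allclose(once.weights, twice.weights)

    def test_commutes_with_subnetwork_extraction(self, rng):
        from cognet.connectome import ThresholdScheme

        stack = np.stack([random_weighted_graph(rng, 8) for _ in range(5)])
        scheme = fit_threshold_scheme(stack)
        labels = [f"n{i}" for i in range(8)]
        members = ["n1", "n3", "n4", "n6"]
        d = SubnetworkDefinition("sub", members)
        c = Connectome(labels, random_weighted_graph(rng, 8))
        idx = d.indices(labels)
        sub_scheme = ThresholdScheme(
            scheme.ctrl_mean[np.ix_(idx, idx)], scheme.ctrl_sd[np.ix_(idx, idx)]
        )
        a = extract_subnetwork(apply_threshold(c, scheme, 2.0), d)
        b = apply_threshold(extract_subnetwork(c, d), sub_scheme, 2.0)
        np.testing.assert_allclose(a.weights, b.weights)

    def test_shape_mismatch_error(self, rng):
        stack = np.stack([random_weighted_graph(rng, 6) for _ in range(3)])
        scheme = fit_threshold_scheme(stack)
        with pytest.raises(ValueError):
            apply_threshold(
                Connectome([f"n{i}" for i in range(4)], random_weighted_graph(rng, 4)),
                scheme,
                2.5,
            )

    def test_transformer_roundtrip_matches_function(self, rng):
        stack = np.stack([random_weighted_graph(rng, 7) for _ in range(5)])
        est = ControlReferencedThreshold(level=2.5).fit(stack)
        w = random_weighted_graph(rng, 7)
        c = apply_threshold(Connectome([f"n{i}" for i in range(7)], w), est.scheme_(), 2.5)
        np.testing.assert_allclose(est.transform(w), c.weights)


class TestExtractSubnetwork:
    def test_all_nodes_identity(self, rng):
        labels = [f"n{i}" for i in range(5)]
        c = Connectome(labels, random_weighted_graph(rng, 5))
        out = extract_subnetwork(c, SubnetworkDefinition("all", labels))
        np.testing.assert_allclose(out.weights, c.weights)

    def test_single_node_is_zero_matrix(self, rng):
        c = Connectome(["a", "b"], random_weighted_graph(rng, 2))
        out = extract_subnetwork(c, SubnetworkDefinition("one", ["b"]))
        assert out.weights.shape == (1, 1)
        assert out.weights[0, 0] == 0.0

    def test_wm_definition_gives_31_nodes(self, atlas):
        c = Connectome(atlas.node_labels, atlas.streamlines.astype(float))
        d = SubnetworkDefinition("working_memory", atlas.wm_members)
        assert extract_subnetwork(c, d).n_nodes == 31

    def test_unknown_member_listed_in_error(self, rng):
        c = Connectome(["a", "b"], random_weighted_graph(rng, 2))
        with pytest.raises(KeyError, match="zz"):
            extract_subnetwork(c, SubnetworkDefinition("bad", ["a", "zz"]))
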