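"""Kabsch alignment, base sampling, CFM loss, and the training loop."""

import numpy as np
import pytest

from tsflow.cgr import build_cgr
from tsflow.errors import ConfigError, InputError
from tsflow.field import FieldConfig, FieldNet
from tsflow.fixtures import make_chiral_pair
from tsflow.flow import (TrainConfig, cfm_loss, make_flow_pair, sample_base,
                         train)
from tsflow.geom import align, kabsch_rotation, random_rotation
from tsflow.nn import Tensor


class _StubField:
    """Duck-typed field returning a fixed velocity for every atom."""

    def __init__(self, value):
        self.value = np.asarray(value, dtype=np.float64)
        self.config = FieldConfig(width=16, n_heads=4)

    def forward_batch(self, coords_list, t_list, cgrs, edge_sets=None):
        n = sum(c.shape[0] for c in coords_list)
        out = np.broadcast_to(self.value, (n, 3)).copy()
        gid = np.concatenate([np.full(c.shape[0], k) for k, c in enumerate(coords_list)])
        return Tensor(out), gid


class TestAlign:
    def test_exact_recovery_under_proper_rotation(self, rng):
        x1 = rng.standard_normal((7, 3))
        x1 -= x1.mean(axis=0)
        r0 = random_rotation(rng)
        aligned = align(x1 @ r0.T + 3.0, x1)
        assert np.sqrt(np.mean(np.sum((aligned - x1) ** 2, axis=1))) < 1e-6

    def test_optimal_among_random_rotations(self, rng):
        for _ in range(5):
            x0 = rng.standard_normal((6, 3))
            x1 = rng.standard_normal((6, 3))
            x1c = x1 - x1.mean(axis=0)
            x0c = x0 - x0.mean(axis=0)
            best = min(np.linalg.norm(x0c @ random_rotation(rng).T - x1c)
                       for _ in range(2000))
            assert np.linalg.norm(align(x0, x1) - x1c) <= best + 1e-9

    def test_chiral_mirror_residual_strictly_positive(self):
        rxn, mirror = make_chiral_pair(0)
        x1 = rxn.ts_geometry.coords
        residual = np.linalg.norm(align(mirror.coords, x1) - (x1 - x1.mean(axis=0)))
        assert residual > 0.3

    def test_rotation_is_always_proper(self, rng):
        for _ in range(10):
            p = rng.standard_normal((4, 3))
            q = rng.standard_normal((4, 3))
            r = kabsch_rotation(p - p.mean(0), q - q.mean(0))
            assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(InputError):
            align(rng.standard_normal((4, 3)), rng.standard_normal((5, 3)))


class TestSampleBase:
    def test_gaussian_reproducible_and_centered(self, rxn):
        a = sample_base(rxn, "gaussian", np.random.default_rng(9))
        b = sample_base(rxn, "gaussian", np.random.default_rng(9))
        assert np.array_equal(a, b)
        assert np.linalg.norm(a.mean(axis=0)) < 1e-6

    def test_single_atom_centers_to_zero(self):
        from tsflow.reaction_io import parse_reaction
        single = parse_reaction("[H:1]>>[H:1]")
        x0 = sample_base(single, "gaussian", np.random.default_rng(0))
        assert np.allclose(x0, 0.0)

    def test_reactant_noise_requires_reactant_geometry(self, rxn):
        import copy
        bare = copy.copy(rxn)
        bare.reactant_geometry = None
        with pytest.raises(ConfigError):
            sample_base(bare, "reactant_noise", np.random.default_rng(0))

    def test_reactant_noise_std_matches_quarter_variance(self, rxn):
        # per-coordinate std of the added noise must be sqrt(0.25) = 0.5 Å
        rng = np.random.default_rng(4)
        n_draws = 2000
        draws = np.stack([sample_base(rxn, "reactant_noise", rng)
                          for _ in range(n_draws)])
        centered_ref = rxn.reactant_geometry.coords \
            - rxn.reactant_geometry.coords.mean(axis=0)
        resid = draws - centered_ref[None]
        assert np.std(resid) == pytest.approx(0.5, rel=0.05)


class TestCfmLoss:
    def test_interpolant_identity_holds_exactly(self, rxn, rng):
        x0 = sample_base(rxn, "gaussian", rng)
        pair = make_flow_pair(x0, rxn.ts_geometry.coords, 0.37)
        assert np.array_equal(pair.x_t, (1 - 0.37) * pair.x0 + 0.37 * pair.x1)
        assert np.linalg.norm(pair.x0.mean(axis=0)) < 1e-6
        assert np.linalg.norm(pair.x1.mean(axis=0)) < 1e-6

    def test_oracle_field_gives_zero_loss(self, rxn, rng):
        cgr = build_cgr(rxn)
        x0 = sample_base(rxn, "gaussian", rng)
        pair = make_flow_pair(x0, rxn.ts_geometry.coords, 0.5)

        class _Oracle(_StubField):
            def forward_batch(self, coords_list, t_list, cgrs, edge_sets=None):
                return Tensor(pair.v_target.copy()), np.zeros(len(pair.x0))

        assert cfm_loss(_Oracle([0, 0, 0]), [pair], [cgr]).data == pytest.approx(0.0)

    def test_zero_field_loss_is_mean_square_target(self, rxn, rng):
        cgr = build_cgr(rxn)
        x0 = sample_base(rxn, "gaussian", rng)
        pair = make_flow_pair(x0, rxn.ts_geometry.coords, 0.2)
        loss = cfm_loss(_StubField([0.0, 0.0, 0.0]), [pair], [cgr])
        assert loss.data == pytest.approx(np.mean(np.sum(pair.v_target ** 2, axis=1)))

    def test_hand_computed_two_atom_value(self):
        # two atoms, constant stub field (1,0,0); targets (+-1, 0, 0)
        x0 = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        x1 = np.array([[-0.5, 0, 0], [1.5, 0, 0]])
        pair = make_flow_pair(x0, x1, 0.5, use_align=False)
        from tsflow.reaction_io import parse_reaction
        cgr = build_cgr(parse_reaction("[H:1][H:2]>>[H:1].[H:2]"))
        loss = cfm_loss(_StubField([1.0, 0.0, 0.0]), [pair], [cgr])
        # centered: x0c = [[-.5,0,0],[.5,0,0]], x1c = [[-1,0,0],[1,0,0]]
        # targets v = x1c - x0c = [[-.5,0,0],[.5,0,0]]
        # stub errors: (1+0.5)^2 = 2.25 and (1-0.5)^2 = 0.25 -> mean 1.25
        assert loss.data == pytest.approx(1.25)

    def test_loss_invariant_under_joint_rotation(self, rxn, tiny_net, rng):
        cgr = build_cgr(rxn)
        x0 = sample_base(rxn, "gaussian", rng)
        pair = make_flow_pair(x0, rxn.ts_geometry.coords, 0.4)
        base = cfm_loss(tiny_net, [pair], [cgr]).data
        r = random_rotation(rng)
        rot = make_flow_pair(pair.x0 @ r.T, pair.x1 @ r.T, 0.4, use_align=False)
        assert cfm_loss(tiny_net, [rot], [cgr]).data == pytest.approx(base, rel=1e-9)


class TestAlignmentStraightensPaths:
    def test_transport_cost_never_increased(self, tiny_dataset, rng):
        for r in tiny_dataset:
            x1 = r.ts_geometry.coords
            x1c = x1 - x1.mean(axis=0)
            x0 = rng.standard_normal(x1.shape)
            cost_aligned = np.sum((align(x0, x1) - x1c) ** 2)
            x0c = x0 - x0.mean(axis=0)
            assert cost_aligned <= np.sum((x0c - x1c) ** 2) + 1e-12

    def test_align_lowers_mean_target_norm_on_scattered_set(self, rxn, rng):
        x1 = rxn.ts_geometry.coords
        on, off = [], []
        for _ in range(50):
            x0 = (rng.standard_normal(x1.shape) @ random_rotation(rng).T) * 2
            on.append(np.sum(make_flow_pair(x0, x1, 0.5, True).v_target ** 2))
            off.append(np.sum(make_flow_pair(x0, x1, 0.5, False).v_target ** 2))
        assert np.mean(on) < np.mean(off)


class TestTrain:
    def test_same_seed_reproduces_loss_curve(self, tiny_dataset):
        cfgs = [TrainConfig(epochs=3, batch_size=4, seed=5) for _ in range(2)]
        curves = []
        for cfg in cfgs:
            net = FieldNet(FieldConfig(width=16, n_layers=2, n_heads=4,
                                       n_rbf=8, seed=7))
            _, hist = train(tiny_dataset[:4], net, cfg)
            curves.append([h["loss"] for h in hist])
        assert curves[0] == curves[1]

    def test_empty_dataset_rejected(self, tiny_net):
        with pytest.raises(ConfigError):
            train([], tiny_net, TrainConfig(epochs=1))

    def test_missing_ts_geometry_rejected(self, tiny_dataset, tiny_net):
        import copy
        broken = [copy.copy(tiny_dataset[0])]
        broken[0].ts_geometry = None
        with pytest.raises(ConfigError):
            train(broken, tiny_net, TrainConfig(epochs=1))

    def test_loss_decreases_on_single_reaction(self, tiny_dataset):
        net = FieldNet(FieldConfig(width=16, n_layers=2, n_heads=4, n_rbf=8, seed=0))
        cfg = TrainConfig(epochs=40, lr=1e-2, draws_per_reaction=32,
                          batch_size=8, seed=1)
        _, hist = train(tiny_dataset[:1], net, cfg)
        assert hist[-1]["loss"] < 0.5 * hist[0]["loss"]
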