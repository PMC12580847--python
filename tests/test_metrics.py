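"""Metric oracles: brute-force recomputation, closed forms, invariances."""

import numpy as np
import pytest

from tsflow.cgr import build_cgr
from tsflow.errors import InputError
from tsflow.fixtures import make_chiral_pair
from tsflow.geom import random_rotation
from tsflow.metrics import (ClashParams, angle_error, d_mae, evaluate, rmsd,
                            steric_clash)
from tsflow.reaction_io import parse_reaction


def _brute_dmae(p, q):
    total, count = 0.0, 0
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            total += abs(np.linalg.norm(p[i] - p[j]) - np.linalg.norm(q[i] - q[j]))
            count += 1
    return total / count


class TestDmae:
    def test_identical_is_zero(self, rng):
        x = rng.standard_normal((6, 3))
        assert d_mae(x, x) == 0.0

    def test_reflection_blind(self, rng):
        x = rng.standard_normal((6, 3))
        assert d_mae(x * np.array([-1, 1, 1]), x) == pytest.approx(0.0, abs=1e-12)

    def test_three_atom_hand_value(self):
        p = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        q = np.array([[0, 0, 0], [2, 0, 0], [0, 1, 0]], dtype=float)
        # pair errors: |1-2|=1, |1-1|=0, |sqrt2-sqrt5|
        expected = (1.0 + 0.0 + abs(np.sqrt(2) - np.sqrt(5))) / 3.0
        assert d_mae(p, q) == pytest.approx(expected)

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            p, q = rng.standard_normal((7, 3)), rng.standard_normal((7, 3))
            assert d_mae(p, q) == pytest.approx(_brute_dmae(p, q), abs=1e-12)

    def test_symmetry_and_rigid_invariance(self, rng):
        p, q = rng.standard_normal((5, 3)), rng.standard_normal((5, 3))
        assert d_mae(p, q) == pytest.approx(d_mae(q, p))
        r = random_rotation(rng, proper=False)
        assert d_mae(p @ r.T + 2, q) == pytest.approx(d_mae(p, q))

    def test_too_few_atoms_rejected(self):
        with pytest.raises(InputError):
            d_mae(np.zeros((1, 3)), np.zeros((1, 3)))


class TestRmsd:
    def test_zero_under_proper_rigid_motion(self, rng):
        x = rng.standard_normal((6, 3))
        r = random_rotation(rng)
        assert rmsd(x @ r.T + 5.0, x) < 1e-9

    def test_chiral_mirror_scores_high(self):
        rxn, mirror = make_chiral_pair(0)
        assert d_mae(mirror, rxn.ts_geometry) == pytest.approx(0.0, abs=1e-9)
        assert rmsd(mirror, rxn.ts_geometry) > 0.3

    def test_beats_random_rotation_search(self, rng):
        p, q = rng.standard_normal((6, 3)), rng.standard_normal((6, 3))
        qc = q - q.mean(axis=0)
        pc = p - p.mean(axis=0)
        best = min(np.sqrt(np.mean(np.sum((pc @ random_rotation(rng).T - qc) ** 2,
                                          axis=1)))
                   for _ in range(2000))
        assert rmsd(p, q) <= best + 1e-9


class TestAngleError:
    WATER = "[H:2][O:1][H:3]>>[H:2][O:1].[H:3]"

    def _water_coords(self, angle_deg):
        a = np.radians(angle_deg)
        return np.array([[0, 0, 0], [0.96, 0, 0],
                         [0.96 * np.cos(a), 0.96 * np.sin(a), 0]])

    def test_single_triplet_hand_value(self):
        cgr = build_cgr(parse_reaction(self.WATER))
        err = angle_error(self._water_coords(109.0), self._water_coords(104.0), cgr)
        assert err == pytest.approx(5.0, abs=1e-9)

    def test_identical_is_zero_and_rigid_invariant(self, rng):
        cgr = build_cgr(parse_reaction(self.WATER))
        x = self._water_coords(104.0)
        assert angle_error(x, x, cgr) == 0.0
        r = random_rotation(rng, proper=False)
        assert angle_error(x @ r.T - 3, x, cgr) == pytest.approx(0.0, abs=1e-9)

    def test_diatomic_returns_undefined_marker(self):
        cgr = build_cgr(parse_reaction("[H:1][H:2]>>[H:1].[H:2]"))
        assert np.isnan(angle_error(np.zeros((2, 3)), np.zeros((2, 3)), cgr))


class TestStericClash:
    def test_no_close_pairs_is_zero(self):
        x = np.array([[0, 0, 0], [1.0, 0, 0], [0, 1.5, 0]])
        assert steric_clash(x) == 0.0

    def test_closed_form_at_sigma(self):
        x = np.array([[0, 0, 0], [0.7, 0, 0]])
        assert steric_clash(x) == pytest.approx(1.0)  # 4·ε·(σ/σ)^12 = 4·0.25

    def test_closed_form_at_half_sigma(self):
        x = np.array([[0, 0, 0], [0.35, 0, 0]])
        assert steric_clash(x) == pytest.approx(4 * 0.25 * 2 ** 12)

    def test_coincident_atoms_flagged_infinite(self):
        assert steric_clash(np.zeros((2, 3))) == np.inf

    def test_monotone_decreasing_toward_cutoff(self):
        vals = [steric_clash(np.array([[0, 0, 0], [r, 0, 0]]))
                for r in np.linspace(0.2, 0.69, 10)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_brute_force_pair_sum(self, rng):
        params = ClashParams()
        x = rng.uniform(0, 1.2, (6, 3))
        expected = 0.0
        for i in range(6):
            for j in range(i + 1, 6):
                r = np.linalg.norm(x[i] - x[j])
                if r <= params.cutoff:
                    expected += 4 * params.epsilon * (params.sigma / r) ** 12
        assert steric_clash(x, params) == pytest.approx(expected, rel=1e-12)


class TestEvaluate:
    def _inputs(self, dataset):
        preds = {r.rxn_id: r.ts_geometry.coords for r in dataset}
        truths = {r.rxn_id: r.ts_geometry.coords for r in dataset}
        cgrs = {r.rxn_id: build_cgr(r) for r in dataset}
        return preds, truths, cgrs

    def test_truth_vs_truth_all_zero(self, tiny_dataset):
        preds, truths, cgrs = self._inputs(tiny_dataset[:3])
        report = evaluate(preds, truths, cgrs)
        assert report.aggregates["d_mae"]["mean"] == 0.0
        assert report.aggregates["rmsd"]["mean"] < 1e-9
        assert report.aggregates["steric_clash"]["mean"] == 0.0

    def test_singleton_aggregate_equals_row(self, tiny_dataset, rng):
        r = tiny_dataset[0]
        pred = r.ts_geometry.coords + rng.normal(0, 0.1, (r.n_atoms, 3))
        report = evaluate({r.rxn_id: pred}, {r.rxn_id: r.ts_geometry.coords},
                          {r.rxn_id: build_cgr(r)})
        row = report.per_reaction.iloc[0]
        assert report.aggregates["d_mae"]["mean"] == pytest.approx(row["d_mae"])

    def test_aggregate_mean_is_hand_mean(self, tiny_dataset, rng):
        subset = tiny_dataset[:3]
        preds = {r.rxn_id: r.ts_geometry.coords + rng.normal(0, 0.05, (r.n_atoms, 3))
                 for r in subset}
        _, truths, cgrs = self._inputs(subset)
        report = evaluate(preds, truths, cgrs)
        hand = np.mean([d_mae(preds[r.rxn_id], truths[r.rxn_id]) for r in subset])
        assert report.aggregates["d_mae"]["mean"] == pytest.approx(hand)

    def test_histogram_counts_sum_to_reaction_count(self, tiny_dataset):
        preds, truths, cgrs = self._inputs(tiny_dataset)
        report = evaluate(preds, truths, cgrs)
        assert sum(report.histogram["counts"]) == len(tiny_dataset)

    def test_id_mismatch_rejected(self, tiny_dataset):
        preds, truths, cgrs = self._inputs(tiny_dataset[:2])
        del preds[tiny_dataset[0].rxn_id]
        with pytest.raises(InputError):
            evaluate(preds, truths, cgrs)
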